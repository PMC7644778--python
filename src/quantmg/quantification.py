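"""Volumetric abundance estimation from internal genomic standards.

Sequencing a known quantity of spiked-in genomic DNA alongside an
environmental sample calibrates absolute quantification: the fraction of
added standard molecules that show up in the library (the recovery ratio R)
converts read counts of any gene category into molecules per sample, and
dividing by the seawater volume filtered yields genes per liter.  Counting a
conserved single-copy gene (recA) per taxon and normalizing the same way
gives genome equivalents — a proxy for cells per liter.

Symbols follow the standard spike-in bookkeeping:

    S_s : protein-encoding internal-standard reads in the library
    S_p : protein-encoding genes in the standard's reference genome
    S_r : standard genome copies recovered,  S_r = S_s / S_p
    S_a : standard genome molecules added,   R   = S_r / S_a
    G_s : reads of any gene category;  molecules G_a = G_s / R
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AVOGADRO",
    "BP_MOLAR_MASS",
    "SpikeStandard",
    "RecoveryRecord",
    "molecules_added",
    "recovery_ratio",
    "gene_abundance",
    "total_protein_genes",
    "genome_equivalents",
    "standards_cv",
    "abundance_ci",
    "detection_limit",
    "abundance_table",
]

#: Avogadro constant (exact, 2019 SI), molecules per mole.
AVOGADRO = 6.02214076e23

#: Mean molar mass of a double-stranded DNA base pair, g mol^-1 bp^-1.
#: The conventional average for dsDNA mass-to-molecule conversions.
BP_MOLAR_MASS = 650.0


class QuantError(ValueError):
    """Invalid input to a quantification operation."""


class UndetectableNormalizationError(QuantError):
    """Nonzero counts cannot be normalized with a zero recovery ratio."""


def molecules_added(
    mass_ng: float,
    genome_length_bp: float,
    *,
    bp_molar_mass: float = BP_MOLAR_MASS,
    avogadro: float = AVOGADRO,
) -> float:
    """Number of genome molecules in ``mass_ng`` nanograms of dsDNA.

    S_a = (mass in g) / (genome_length × bp molar mass) × N_A.

    >>> round(molecules_added(4, 2e6) / 1e6, 3)
    1.853
    """
    if mass_ng <= 0 or genome_length_bp <= 0:
        raise QuantError(
            f"mass and genome length must be positive, got {mass_ng} ng, "
            f"{genome_length_bp} bp"
        )
    grams = mass_ng * 1e-9
    return grams / (genome_length_bp * bp_molar_mass) * avogadro


@dataclass(frozen=True)
class SpikeStandard:
    """An internal genomic standard spiked into a sample before extraction.

    Either ``S_a`` (molecules added) is given directly, or it is derived from
    ``mass_added_ng`` and ``genome_length_bp``.
    """

    standard_id: str
    S_p: int
    genome_length_bp: float
    S_a: float | None = None
    mass_added_ng: float | None = None

    def __post_init__(self) -> None:
        if self.S_p < 1:
            raise QuantError(f"S_p must be >= 1, got {self.S_p}")
        if self.S_a is None and self.mass_added_ng is None:
            raise QuantError("either S_a or mass_added_ng is required")
        if self.S_a is None:
            object.__setattr__(
                self,
                "S_a",
                molecules_added(self.mass_added_ng, self.genome_length_bp),
            )
        elif self.mass_added_ng is not None:
            expected = molecules_added(self.mass_added_ng, self.genome_length_bp)
            if not math.isclose(self.S_a, expected, rel_tol=1e-6):
                raise QuantError(
                    f"S_a={self.S_a:g} inconsistent with mass "
                    f"{self.mass_added_ng} ng of a {self.genome_length_bp:g} bp "
                    f"genome (expected {expected:g})"
                )
        if self.S_a <= 0:
            raise QuantError(f"S_a must be positive, got {self.S_a}")


@dataclass(frozen=True)
class RecoveryRecord:
    """Recovery of one standard in one sample."""

    sample_id: str
    standard_id: str
    S_s: int
    S_r: float
    R: float


def recovery_ratio(S_s: float, S_p: float, S_a: float) -> tuple[float, float]:
    """Standard genome copies recovered and the recovery ratio.

    S_r = S_s / S_p ; R = S_r / S_a.
    """
    if S_p < 1:
        raise QuantError(f"S_p must be >= 1, got {S_p}")
    if S_a <= 0:
        raise QuantError(f"S_a must be positive, got {S_a}")
    if S_s < 0:
        raise QuantError(f"S_s must be >= 0, got {S_s}")
    S_r = S_s / S_p
    return S_r, S_r / S_a


def gene_abundance(G_s: float, R: float, V: float) -> float:
    """Volumetric abundance (genes per liter) of a gene category.

    ``G_s`` reads normalized by the recovery ratio gives molecules in the
    sample; dividing by the volume filtered ``V`` (liters) gives genes L^-1.
    """
    if V <= 0:
        raise QuantError(f"volume must be positive, got {V}")
    if R < 0:
        raise QuantError(f"recovery ratio must be >= 0, got {R}")
    if R == 0:
        if G_s == 0:
            warnings.warn(
                "zero recovery ratio with zero counts; abundance reported as 0",
                stacklevel=2,
            )
            return 0.0
        raise UndetectableNormalizationError(
            f"cannot normalize {G_s} reads with R=0"
        )
    return (G_s / R) / V


def total_protein_genes(total_annotated_reads: float, R: float, V: float) -> float:
    """Total protein-encoding genes per liter: all annotated reads over R and V."""
    return gene_abundance(total_annotated_reads, R, V)


def genome_equivalents(recA_count: float, R: float, V: float) -> float:
    """Genome equivalents (cells per liter) from single-copy recA counts.

    recA is present once per bacterial genome, so recA reads normalized by R
    and V estimate genomes — and hence cells — per liter.
    """
    return gene_abundance(recA_count, R, V)


def standards_cv(R_values) -> float:
    """Percent coefficient of variation across the three standards' R.

    %CV = sample standard deviation (n-1 denominator) / mean × 100.
    """
    r = np.asarray(R_values, dtype=float)
    if r.size != 3:
        raise QuantError(f"expected exactly 3 recovery ratios, got {r.size}")
    mean = r.mean()
    if mean == 0:
        raise QuantError("undefined %CV: mean recovery ratio is 0")
    return float(r.std(ddof=1) / mean * 100.0)


def abundance_ci(
    per_standard_abundances, confidence: float = 0.95
) -> tuple[float, float] | None:
    """Two-sided t confidence interval from the three per-standard estimates.

    mean ± t_{(1+c)/2, df=2} × sd/√3, with the lower bound floored at 0.
    Returns ``None`` (with a warning) when fewer than three estimates are
    available.
    """
    a = np.asarray(per_standard_abundances, dtype=float)
    if a.size < 3:
        warnings.warn(
            f"CI undefined with {a.size} standards (3 required)", stacklevel=2
        )
        return None
    if a.size != 3:
        raise QuantError(f"expected exactly 3 estimates, got {a.size}")
    t = stats.t.ppf(0.5 + confidence / 2.0, df=a.size - 1)
    half = t * a.std(ddof=1) / math.sqrt(a.size)
    mean = a.mean()
    return max(0.0, mean - half), mean + half


def detection_limit(
    R: float, V: float, *, method: str = "expected-one", prob: float = 0.95
) -> float:
    """Smallest abundance (cells L^-1) detectable in a sample.

    ``expected-one`` (default): abundance whose expected recA read count is
    exactly 1, i.e. 1/(R·V).  ``poisson``: abundance where the Poisson
    probability of observing at least one read reaches ``prob``, i.e.
    -ln(1-prob)/(R·V).
    """
    if R <= 0 or V <= 0:
        raise QuantError(f"R and V must be positive, got R={R}, V={V}")
    if method == "expected-one":
        return 1.0 / (R * V)
    if method == "poisson":
        return -math.log(1.0 - prob) / (R * V)
    raise QuantError(f"unknown detection-limit method: {method!r}")


def _sample_recoveries(
    recovery: pd.DataFrame, standards: dict[str, SpikeStandard]
) -> pd.DataFrame:
    """Per (sample, standard) S_r and R from raw S_s counts."""
    rec = recovery.copy()
    missing = set(rec["standard_id"]) - set(standards)
    if missing:
        raise QuantError(f"unknown standards in recovery table: {sorted(missing)}")
    sp = rec["standard_id"].map(lambda s: standards[s].S_p)
    sa = rec["standard_id"].map(lambda s: standards[s].S_a)
    rec["S_r"] = rec["S_s"] / sp
    rec["R"] = rec["S_r"] / sa
    return rec


def abundance_table(
    counts: pd.DataFrame,
    recovery: pd.DataFrame,
    standards: dict[str, SpikeStandard] | list[SpikeStandard],
    volumes: pd.Series,
) -> pd.DataFrame:
    """Tidy volumetric abundance table with per-standard confidence intervals.

    Parameters
    ----------
    counts
        Tidy frame with columns ``sample_id``, ``taxon`` (or ``family``) and
        ``count`` — single-copy-gene reads per taxon per sample.
    recovery
        Tidy frame with columns ``sample_id``, ``standard_id``, ``S_s``.
    standards
        The spiked standards (three for CI support).
    volumes
        Seawater volume filtered per sample, liters, indexed by sample_id.

    Returns
    -------
    DataFrame with one row per (taxon, sample): ``cells_per_L`` from the
    pooled mean R, ``ci_low``/``ci_high`` from the per-standard estimates,
    ``R_mean``, ``cv_percent`` and the sample ``detection_limit``.  Zero
    counts are reported as 0 cells L^-1 (never missing) with the detection
    limit attached.
    """
    if isinstance(standards, list):
        standards = {s.standard_id: s for s in standards}
    key = "taxon" if "taxon" in counts.columns else "family"
    rec = _sample_recoveries(recovery, standards)
    r_by_sample = rec.pivot(index="sample_id", columns="standard_id", values="R")

    rows = []
    for _, row in counts.iterrows():
        sid = row["sample_id"]
        if sid not in r_by_sample.index:
            raise QuantError(f"no recovery records for sample {sid!r}")
        r_vals = r_by_sample.loc[sid].dropna().to_numpy()
        r_mean = r_vals.mean()
        V = float(volumes[sid])
        n = float(row["count"])
        point = gene_abundance(n, r_mean, V)
        if n == 0:
            ci = (0.0, 0.0)
        elif r_vals.size == 3 and (r_vals > 0).all():
            per_std = [gene_abundance(n, r, V) for r in r_vals]
            ci = abundance_ci(per_std)
        else:
            # a standard with zero recovery leaves no per-standard estimate
            ci = None
        rows.append(
            {
                key: row[key],
                "sample_id": sid,
                "count": n,
                "cells_per_L": point,
                "ci_low": ci[0] if ci else np.nan,
                "ci_high": ci[1] if ci else np.nan,
                "R_mean": r_mean,
                "cv_percent": standards_cv(r_vals) if r_vals.size == 3 else np.nan,
                "detection_limit": detection_limit(r_mean, V),
            }
        )
    return pd.DataFrame(rows)
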