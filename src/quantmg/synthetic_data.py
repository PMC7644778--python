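"""Synthetic spike-in metagenomics scenarios with known ground truth.

Generates everything the downstream pipeline consumes — a reference
collection (taxa with genome sizes, protein-gene counts and a single recA
gene each), three internal genomic standards, ground-truth communities laid
out over an archipelago-like design (five regions on a west→east axis, two
sampling years), and simulated annotation hit tables — so every stage of
the analysis can be tested against a known answer.

The sampling model works at the gene-molecule level: a sample's library of
``reads_per_sample`` reads is drawn multinomially over taxa and standards,
where a taxon's weight is abundance × volume × protein-gene count (its
protein-encoding gene molecules in the filtered water) and a standard's
weight is S_a × S_p (molecules added × genes per genome).  Within a taxon's
reads, recA reads are Bernoulli with p = 1/protein_gene_count, enforcing
single-copy semantics exactly.  Annotation noise is injected per read: a
``misannotation_rate`` fraction of community reads receives a sub-50-bit
protein hit (later filtered), and a ``dual_hit_rate`` fraction receives
both a bacterial and a viral hit with independent bit scores, exercising
the viral-override arbitration.

Reads are simulated at the annotation-count level (hit-table rows), not as
nucleotide sequences: read QC, merging and the homology searches themselves
sit upstream of this package's boundary.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hit_filtering import HIT_COLUMNS
from .quantification import SpikeStandard, molecules_added

__all__ = [
    "REGIONS",
    "ReferenceTaxon",
    "TrueCommunity",
    "SimConfig",
    "SampleSim",
    "Scenario",
    "generate_reference_collection",
    "generate_community_scenario",
    "simulate_sequencing",
    "simulate_scenario",
    "write_fixture_set",
    "read_fixture_set",
]

#: Regions ordered along the west→east axis of the sampling design.
REGIONS = ("west", "north", "central", "caldera", "east")

#: The three spiked genomes: id, genome length (bp).  Sizes emulate the
#: thermophile / radiation-resistant / gut-anaerobe genomic standards
#: commonly spiked into seawater samples (none occur in the community).
STANDARD_GENOMES = (
    ("Thermus_thermophilus", 2_130_000),
    ("Deinococcus_radiodurans", 3_280_000),
    ("Blautia_producta", 6_090_000),
)


class SimError(ValueError):
    """Invalid simulator configuration or degenerate input."""


@dataclass(frozen=True)
class ReferenceTaxon:
    """A community reference genome: one family, one recA gene."""

    taxon_id: str
    family: str
    genome_length: int
    protein_gene_count: int
    has_recA: bool = True
    reference_bin_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.protein_gene_count < 1:
            raise SimError("protein_gene_count must be >= 1")
        if self.genome_length < self.protein_gene_count:
            raise SimError("genes must fit in the genome")
        if self.has_recA and not self.reference_bin_ids:
            object.__setattr__(self, "reference_bin_ids", (f"{self.taxon_id}_bin1",))


@dataclass
class TrueCommunity:
    """Ground truth for one sample: cells per liter for every taxon."""

    sample_id: str
    site: str
    region: str
    year: int
    taxon_abundances: pd.Series  # taxon_id -> cells L^-1
    volume_filtered: float       # liters

    def __post_init__(self) -> None:
        a = self.taxon_abundances
        if not np.isfinite(a).all() or (a < 0).any():
            raise SimError(f"abundances must be finite and >= 0 in {self.sample_id}")
        if self.volume_filtered <= 0:
            raise SimError("volume_filtered must be > 0")


@dataclass
class SimConfig:
    """Study-design knobs for the simulator.

    Defaults describe a desk-scale archipelago survey: 50 families over 150
    taxa, two sites per region across five west→east regions, two sampling
    years, 2 L filtered per sample, surface-pelagic total abundances around
    2×10^9 cells L^-1, three 4-ng genomic standards, and light annotation
    noise (1% sub-threshold hits, 1% dual bacterial/viral hits).
    """

    n_families: int = 50
    n_taxa: int = 150
    n_sites_per_region: int | dict = 2
    years: tuple = (1, 2)
    elnino_year: int = 1
    gradient_log10_span: float = 1.5
    gradient_families: dict | None = None   # family -> log10 span (signed)
    elnino_indicator_families: dict = field(default_factory=dict)  # family -> multiplier
    reads_per_sample: int = 100_000
    standard_mass_ng: float = 4.0
    misannotation_rate: float = 0.01
    dual_hit_rate: float = 0.01
    lognormal_sd_log10: float = 0.3
    volume_L: float = 2.0
    total_abundance_target: float = 2e9
    total_abundance_bounds: tuple = (1e8, 1e10)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("misannotation_rate", "dual_hit_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise SimError(f"{name} must be in [0, 1], got {p}")
        for name in ("n_families", "n_taxa", "reads_per_sample"):
            if getattr(self, name) < 1:
                raise SimError(f"{name} must be >= 1")
        if self.n_taxa < self.n_families:
            raise SimError(
                f"n_taxa ({self.n_taxa}) must be >= n_families ({self.n_families})"
            )
        if self.lognormal_sd_log10 < 0:
            raise SimError("lognormal_sd_log10 must be >= 0")
        if self.volume_L <= 0:
            raise SimError("volume_L must be > 0")
        # normalize sequence fields so YAML round-trips compare equal
        self.years = tuple(self.years)
        self.total_abundance_bounds = tuple(self.total_abundance_bounds)

    def sites_per_region(self) -> dict:
        if isinstance(self.n_sites_per_region, dict):
            return {r: int(self.n_sites_per_region[r]) for r in REGIONS}
        return {r: int(self.n_sites_per_region) for r in REGIONS}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d


@dataclass
class SampleSim:
    """Simulated sequencing of one sample.

    ``counts`` is the truth-linked annotated-counts table (one row per taxon
    or standard) and ``hit_tables`` the materialized BLAST-tabular frames
    (present when hits were emitted).
    """

    sample_id: str
    counts: pd.DataFrame
    hit_tables: dict | None = None


@dataclass
class Scenario:
    """A complete simulated study: config, references, truth and libraries."""

    config: SimConfig
    taxa: list
    standards: list
    communities: list
    sims: dict = field(default_factory=dict)       # sample_id -> SampleSim
    subject_titles: pd.DataFrame | None = None
    gradient_families: dict = field(default_factory=dict)

    @property
    def taxon_family(self) -> pd.Series:
        return pd.Series({t.taxon_id: t.family for t in self.taxa})

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for c in self.communities:
            for taxon, cells in c.taxon_abundances.items():
                rows.append(
                    {"sample_id": c.sample_id, "taxon_id": taxon, "cells_per_L": cells}
                )
        return pd.DataFrame(rows)

    def metadata_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id,
                    "site": c.site,
                    "region": c.region,
                    "year": c.year,
                    "volume_L": c.volume_filtered,
                }
                for c in self.communities
            ]
        )


# ---------------------------------------------------------------------------
# reference collection
# ---------------------------------------------------------------------------

def generate_reference_collection(
    config: SimConfig,
) -> tuple[list, list]:
    """Taxa plus the three spiked standards, deterministic under the seed.

    Genome lengths are log-uniform on [1.3, 9] Mbp — the realistic span for
    marine bacterioplankton through copiotrophs — and protein-gene counts
    follow the one-gene-per-kilobase rule of thumb (rounded, at least 1).
    Every taxon carries exactly one recA gene.  The standards are flagged
    non-community by construction (they are returned separately and carry
    S_a computed from the spiked mass).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    n_t, n_f = config.n_taxa, config.n_families
    families = [f"F{i + 1:03d}" for i in range(n_f)]
    # every family gets at least one taxon; the rest are assigned at random
    assignment = list(range(n_f)) + list(rng.integers(0, n_f, size=n_t - n_f))
    lengths = np.exp(
        rng.uniform(np.log(1.3e6), np.log(9e6), size=n_t)
    ).round().astype(int)
    taxa = []
    for i in range(n_t):
        tid = f"T{i + 1:04d}"
        n_bins = int(rng.integers(1, 4))
        taxa.append(
            ReferenceTaxon(
                taxon_id=tid,
                family=families[assignment[i]],
                genome_length=int(lengths[i]),
                protein_gene_count=max(1, round(lengths[i] / 1000)),
                reference_bin_ids=tuple(f"{tid}_bin{k + 1}" for k in range(n_bins)),
            )
        )
    standards = [
        SpikeStandard(
            standard_id=sid,
            S_p=max(1, round(length / 1000)),
            genome_length_bp=length,
            mass_added_ng=config.standard_mass_ng,
        )
        for sid, length in STANDARD_GENOMES
    ]
    return taxa, standards


# ---------------------------------------------------------------------------
# ground-truth communities
# ---------------------------------------------------------------------------

def _resolve_gradient_families(config: SimConfig, families: list) -> dict:
    """Default spatial structure: a tenth of families increase 10^span
    west→east and another tenth decrease, emulating the oligotrophic-east /
    upwelling-west contrast."""
    if config.gradient_families is not None:
        unknown = set(config.gradient_families) - set(families)
        if unknown:
            raise SimError(f"unknown gradient families: {sorted(unknown)}")
        return dict(config.gradient_families)
    k = max(1, len(families) // 10)
    span = config.gradient_log10_span
    out = {f: span for f in families[:k]}
    out.update({f: -span for f in families[k: 2 * k]})
    return out


def generate_community_scenario(config: SimConfig, collection) -> Scenario:
    """Ground-truth communities across sites, regions and years.

    Per-taxon baseline abundances are log-normal (a wide, realistic
    rank-abundance curve rescaled so the expected community total matches
    ``total_abundance_target``).  Designated gradient families change by
    10^span multiplicatively and monotonically along the west→east site
    axis; El Niño indicator families are multiplied by their year-effect in
    the El Niño year only; every sample adds independent log-normal noise
    (sd ``lognormal_sd_log10`` log10 units).
    """
    taxa, standards = collection
    families = sorted({t.family for t in taxa})
    unknown = set(config.elnino_indicator_families) - set(families)
    if unknown:
        raise SimError(f"unknown El Niño indicator families: {sorted(unknown)}")
    gradient = _resolve_gradient_families(config, families)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    taxon_ids = [t.taxon_id for t in taxa]
    fam_of = np.array([t.family for t in taxa])
    base = 10.0 ** rng.normal(0.0, 1.0, size=len(taxa))
    base *= config.total_abundance_target / base.sum()

    prefix = {"west": "W", "north": "N", "central": "C", "caldera": "K", "east": "E"}
    sites = []
    for region in REGIONS:
        for s in range(config.sites_per_region()[region]):
            sites.append((f"{prefix[region]}{s + 1}", region))
    n_sites = len(sites)
    communities = []
    for si, (site, region) in enumerate(sites):
        axis = si / (n_sites - 1) if n_sites > 1 else 0.0
        grad_mult = np.ones(len(taxa))
        for fam, span in gradient.items():
            grad_mult[fam_of == fam] = 10.0 ** (span * (axis - 0.5))
        for year in config.years:
            year_mult = np.ones(len(taxa))
            if year == config.elnino_year:
                for fam, mult in config.elnino_indicator_families.items():
                    year_mult[fam_of == fam] = mult
            noise = 10.0 ** rng.normal(0.0, config.lognormal_sd_log10, size=len(taxa))
            cells = base * grad_mult * year_mult * noise
            communities.append(
                TrueCommunity(
                    sample_id=f"{site}_y{year}",
                    site=site,
                    region=region,
                    year=year,
                    taxon_abundances=pd.Series(cells, index=taxon_ids),
                    volume_filtered=config.volume_L,
                )
            )
    # one global rescale pins the geometric-mean total to the target while
    # preserving every gradient and year-effect ratio exactly
    totals = np.array([c.taxon_abundances.sum() for c in communities])
    scale = config.total_abundance_target / np.exp(np.log(totals).mean())
    lo, hi = config.total_abundance_bounds
    for c in communities:
        c.taxon_abundances = c.taxon_abundances * scale
        total = c.taxon_abundances.sum()
        if not lo <= total <= hi:
            # clamp the rare tail sample to the bound, keeping composition
            clamped = min(max(total, lo), hi)
            warnings.warn(
                f"{c.sample_id}: total {total:.3g} cells/L clamped to "
                f"{clamped:g}",
                stacklevel=2,
            )
            c.taxon_abundances = c.taxon_abundances * (clamped / total)
    return Scenario(
        config=config,
        taxa=taxa,
        standards=standards,
        communities=communities,
        gradient_families=gradient,
    )


def elnino_indicator_defaults(
    config: SimConfig,
    collection,
    k: int = 4,
    multipliers: tuple = (0.1, 10.0),
) -> dict:
    """Year-effect multipliers for the ``k`` most abundant families.

    An El Niño-like disturbance reorganizes the *dominant* fraction of the
    community — upwelling-adapted populations collapse by an order of
    magnitude while warm-water taxa bloom — so the emulated year effect is
    applied to the families that carry the most baseline abundance, with
    alternating down/up multipliers.  The baseline ranking is taken from
    the same seed's no-effect scenario, so the returned mapping is
    deterministic given the config.
    """
    base_cfg = dataclasses.replace(config, elnino_indicator_families={})
    baseline = generate_community_scenario(base_cfg, collection)
    truth = baseline.truth_table()
    truth["family"] = truth["taxon_id"].map(baseline.taxon_family)
    top = truth.groupby("family")["cells_per_L"].sum().nlargest(k).index
    return {f: multipliers[i % len(multipliers)] for i, f in enumerate(top)}


# ---------------------------------------------------------------------------
# sequencing simulation
# ---------------------------------------------------------------------------

def _subject_titles(taxa, standards) -> pd.DataFrame:
    """Product titles for every simulated protein subject (needed for the
    recA-confirmation step and the viral-override arbitration)."""
    rows = []
    for t in taxa:
        rows.append(
            {"sseqid": f"{t.taxon_id}_recA", "title": f"protein RecA [{t.taxon_id}]"}
        )
        rows.append(
            {
                "sseqid": f"{t.taxon_id}_p1",
                "title": f"hypothetical protein [{t.taxon_id}]",
            }
        )
    for s in standards:
        rows.append(
            {"sseqid": f"{s.standard_id}_p1", "title": f"conserved protein [{s.standard_id}]"}
        )
    rows.append({"sseqid": "vir_p1", "title": "portal protein [uncultured phage]"})
    return pd.DataFrame(rows)


def simulate_sequencing(
    community: TrueCommunity,
    standards,
    collection_taxa,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    emit_hits: bool = False,
) -> SampleSim:
    """Draw one sample's library and (optionally) its hit tables.

    Reads are multinomial over taxa and standards with gene-molecule
    weights; per-read recA, misannotation and dual-hit flags follow the
    configured probabilities (dual hits are drawn among non-misannotated
    reads, and a dual read's viral hit out-scores its bacterial hit with
    probability ½ since the two bit scores are independent and identically
    distributed).  The returned counts table records, per category, the
    reads drawn and how many survive each downstream filter; read totals sum
    exactly to ``reads_per_sample``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = np.array([t.protein_gene_count for t in collection_taxa], dtype=float)
    abund = community.taxon_abundances.reindex(
        [t.taxon_id for t in collection_taxa]
    ).to_numpy()
    V = community.volume_filtered
    w_taxa = abund * V * genes
    w_std = np.array([s.S_a * s.S_p for s in standards], dtype=float)
    w = np.concatenate([w_taxa, w_std])
    if w.sum() <= 0:
        raise SimError(f"zero total sampling weight in {community.sample_id}")
    counts = rng.multinomial(config.reads_per_sample, w / w.sum())
    n_taxa = len(collection_taxa)

    rows = []
    per_read: list = []  # (kind, index, reca, mis, dual, viral_won) blocks
    for i, t in enumerate(collection_taxa):
        n = int(counts[i])
        if n == 0:
            rows.append(
                dict(category_id=t.taxon_id, kind="taxon", n_reads=0, n_reca=0,
                     n_misannotated=0, n_dual=0, n_dual_viral=0, n_reca_counted=0)
            )
            continue
        reca = rng.random(n) < 1.0 / t.protein_gene_count
        mis = rng.random(n) < config.misannotation_rate
        dual = (~mis) & (rng.random(n) < config.dual_hit_rate)
        viral_won = dual & (rng.random(n) < 0.5)
        counted = reca & ~mis & ~viral_won
        rows.append(
            dict(
                category_id=t.taxon_id, kind="taxon", n_reads=n,
                n_reca=int(reca.sum()), n_misannotated=int(mis.sum()),
                n_dual=int(dual.sum()), n_dual_viral=int(viral_won.sum()),
                n_reca_counted=int(counted.sum()),
            )
        )
        if emit_hits:
            per_read.append(("taxon", i, reca, mis, dual, viral_won))
    for j, s in enumerate(standards):
        n = int(counts[n_taxa + j])
        rows.append(
            dict(category_id=s.standard_id, kind="standard", n_reads=n, n_reca=0,
                 n_misannotated=0, n_dual=0, n_dual_viral=0, n_reca_counted=0)
        )
        if emit_hits and n:
            per_read.append(("standard", j, None, None, None, None))
    counts_df = pd.DataFrame(rows)
    counts_df.insert(0, "sample_id", community.sample_id)

    hit_tables = None
    if emit_hits:
        hit_tables = _emit_hit_tables(
            community.sample_id, counts, per_read, collection_taxa, standards, rng
        )
    return SampleSim(community.sample_id, counts_df, hit_tables)


def _blast_rows(qseqid, sseqid, pident, length, qlen, evalue, bitscore, sset):
    """Assemble a plausible 14-column BLAST-tabular frame from the columns
    the pipeline actually reads; positional columns are filled consistently."""
    length = np.asarray(length)
    mismatch = np.round(length * (1 - np.asarray(pident) / 100.0)).astype(int)
    return pd.DataFrame(
        {
            "qseqid": qseqid,
            "sseqid": sseqid,
            "pident": np.round(pident, 2),
            "length": length,
            "mismatch": mismatch,
            "gapopen": 0,
            "qstart": 1,
            "qend": length,
            "sstart": 1,
            "send": length,
            "evalue": evalue,
            "bitscore": np.round(bitscore, 1),
            "qlen": qlen,
            "sset": sset,
        }
    )


def _emit_hit_tables(sample_id, counts, per_read, taxa, standards, rng):
    """Materialize BLAST-tabular hit tables from the per-read draws.

    Filtering these tables through the arbitration pipeline reproduces the
    counts table exactly (asserted in the test suite).
    """
    read_len = 150
    frames = {k: [] for k in
              ("standard_nuc", "standard_prot", "refseq_prot", "viral_prot", "recA_prot")}
    next_read = 0
    for kind, idx, reca, mis, dual, viral_won in per_read:
        if kind == "standard":
            s = standards[idx]
            n = int(counts[len(taxa) + idx])
            rids = [f"{sample_id}_r{next_read + k:07d}" for k in range(n)]
            next_read += n
            aln = rng.integers(80, read_len + 1, size=n)
            frames["standard_nuc"].append(
                _blast_rows(rids, s.standard_id, rng.uniform(96, 100, n), aln,
                            read_len, 1e-30, rng.uniform(60, 200, n), "standard_nuc")
            )
            frames["standard_prot"].append(
                _blast_rows(rids, f"{s.standard_id}_p1", rng.uniform(95, 100, n),
                            (aln // 3).clip(min=20), read_len, 1e-20,
                            rng.uniform(50, 180, n), "standard_prot")
            )
            continue
        t = taxa[idx]
        n = int(counts[idx])
        rids = np.array([f"{sample_id}_r{next_read + k:07d}" for k in range(n)])
        next_read += n
        # community all-protein hits: recA reads hit the taxon's recA
        # protein, others a generic protein; misannotated reads score < 50
        sseq = np.where(reca, f"{t.taxon_id}_recA", f"{t.taxon_id}_p1")
        bits = rng.uniform(60, 200, n)
        bits[mis] = rng.uniform(20, 49.9, int(mis.sum()))
        # dual reads: the two bit scores are iid; order them per the flag
        b1 = rng.uniform(60, 200, n)
        b2 = rng.uniform(60, 200, n)
        hi, lo = np.maximum(b1, b2), np.minimum(b1, b2)
        bact_bits = bits.copy()
        vir_bits = np.empty(n)
        take = dual & viral_won
        bact_bits[take], vir_bits[take] = lo[take], hi[take]
        take = dual & ~viral_won
        bact_bits[take], vir_bits[take] = hi[take], lo[take]
        frames["refseq_prot"].append(
            _blast_rows(rids, sseq, rng.uniform(70, 100, n),
                        (rng.integers(90, read_len + 1, n) // 3), read_len,
                        1e-10, bact_bits, "refseq_prot")
        )
        if dual.any():
            d = dual
            frames["viral_prot"].append(
                _blast_rows(rids[d], "vir_p1", rng.uniform(70, 100, int(d.sum())),
                            read_len // 3, read_len, 1e-10, vir_bits[d], "viral_prot")
            )
        if reca.any():
            r = reca
            frames["recA_prot"].append(
                _blast_rows(rids[r], f"{t.taxon_id}_recA",
                            rng.uniform(80, 100, int(r.sum())), read_len // 3,
                            read_len, 1e-15, rng.uniform(60, 200, int(r.sum())),
                            "recA_prot")
            )
    out = {}
    for name, parts in frames.items():
        out[name] = (
            pd.concat(parts, ignore_index=True)
            if parts
            else pd.DataFrame(columns=HIT_COLUMNS)
        )
    return out


def simulate_scenario(
    config: SimConfig | None = None,
    scenario: Scenario | None = None,
    emit_hits: bool = False,
) -> Scenario:
    """End-to-end generation: collection → communities → libraries.

    Per-sample RNG streams are spawned from the config seed, so the whole
    scenario is byte-identical on rerun and individual samples are
    independent.
    """
    if scenario is None:
        if config is None:
            config = SimConfig()
        collection = generate_reference_collection(config)
        scenario = generate_community_scenario(config, collection)
    config = scenario.config
    sim_parent = np.random.SeedSequence(config.seed).spawn(3)[2]
    children = sim_parent.spawn(len(scenario.communities))
    for community, child in zip(scenario.communities, children):
        scenario.sims[community.sample_id] = simulate_sequencing(
            community,
            scenario.standards,
            scenario.taxa,
            config,
            rng=np.random.default_rng(child),
            emit_hits=emit_hits,
        )
    scenario.subject_titles = _subject_titles(scenario.taxa, scenario.standards)
    return scenario


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def write_fixture_set(scenario: Scenario, path) -> dict:
    """Write a scenario to a directory of plain-text tables plus a manifest.

    Emits per-sample hit tables (when materialized), sample metadata, the
    ground-truth table, standards, the reference collection, subject titles
    and the config; the manifest lists every file with its row count.
    Reloading with :func:`read_fixture_set` round-trips the tables exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": scenario.config.seed, "files": {}}

    def _write(name: str, df: pd.DataFrame) -> None:
        df.to_csv(path / name, sep="\t", index=False)
        manifest["files"][name] = int(len(df))

    _write("metadata.tsv", scenario.metadata_table())
    _write("truth.tsv", scenario.truth_table())
    _write(
        "standards.tsv",
        pd.DataFrame(
            [
                {
                    "standard_id": s.standard_id,
                    "S_p": s.S_p,
                    "S_a": s.S_a,
                    "genome_length_bp": s.genome_length_bp,
                    "mass_added_ng": s.mass_added_ng,
                }
                for s in scenario.standards
            ]
        ),
    )
    _write(
        "reference_collection.tsv",
        pd.DataFrame(
            [
                {
                    "taxon_id": t.taxon_id,
                    "family": t.family,
                    "genome_length": t.genome_length,
                    "protein_gene_count": t.protein_gene_count,
                    "has_recA": t.has_recA,
                    "reference_bin_ids": ",".join(t.reference_bin_ids),
                }
                for t in scenario.taxa
            ]
        ),
    )
    if scenario.subject_titles is not None:
        _write("subject_titles.tsv", scenario.subject_titles)
    counts = [s.counts for s in scenario.sims.values()]
    if counts:
        _write("annotated_counts.tsv", pd.concat(counts, ignore_index=True))
    for sid, sim in scenario.sims.items():
        if sim.hit_tables:
            for name, df in sim.hit_tables.items():
                _write(f"hits_{sid}_{name}.tsv", df)
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(scenario.config.to_dict(), fh)
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return manifest


def read_fixture_set(path) -> dict:
    """Load a fixture directory written by :func:`write_fixture_set`.

    Validates the manifest (every listed file must exist with the recorded
    row count; the truth table is mandatory) and returns the tables keyed by
    file stem, plus the config.
    """
    path = Path(path)
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    if "truth.tsv" not in manifest["files"]:
        raise SimError("fixture set has no truth table")
    out: dict = {"manifest": manifest}
    for name, n_rows in manifest["files"].items():
        fp = path / name
        if not fp.exists():
            raise SimError(f"manifest lists missing file: {name}")
        df = pd.read_csv(fp, sep="\t")
        if len(df) != n_rows:
            raise SimError(
                f"{name}: {len(df)} rows, manifest says {n_rows}"
            )
        out[name.removesuffix(".tsv")] = df
    with open(path / "config.yaml") as fh:
        out["config"] = SimConfig(**yaml.safe_load(fh))
    return out
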