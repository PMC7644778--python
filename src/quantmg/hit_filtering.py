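"""Annotation arbitration for spike-in metagenomics hit tables.

Consumes BLAST/DIAMOND tabular output (outfmt 6 plus a query-length column)
from four homology searches — standard genomes (nucleotide), standard
proteins, all bacterial/archaeal proteins, viral proteins — plus a RecA
protein search, and applies the arbitration rules that turn raw hits into
countable annotations:

* internal-standard reads are identified from the nucleotide search by four
  strict cutoffs (e-value < 0.001, %ID > 95, alignment > 50% of read length,
  bit score > 50) and removed from community annotation;
* standard protein-encoding reads (S_s) are counted after removing protein
  hits with bit score < 40 or %ID < 95;
* community protein hits keep the top hit per read, dropping bit < 50;
* a bacterial annotation is replaced by a viral one when the viral hit has a
  strictly higher bit score;
* a read counts as recA when its top hit against the RecA database scores
  above 50 bits and the all-protein search confirms a RecA product title.

All cutoffs are centralized in :data:`THRESHOLDS`; comparisons written
strictly ("<", ">") are applied strictly, so e.g. a 95.0 %ID hit is *not* a
standard read and a 40-bit standard protein hit *is* counted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HIT_COLUMNS",
    "THRESHOLDS",
    "RECA_KEYWORDS",
    "Hit",
    "ReadPartition",
    "read_hit_table",
    "select_top_hit",
    "select_top_hits",
    "identify_standard_reads",
    "count_standard_protein_reads",
    "viral_override",
    "arbitrate_annotations",
    "build_recA_database_membership",
    "count_recA",
]

#: BLAST tabular (outfmt 6) columns plus the query-length extension (qlen)
#: and the subject-set label this package appends.
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "qlen", "sset",
]

#: Every cutoff used by the arbitration, in one place.  Strict comparisons
#: mirror how the filters are stated: removal conditions written with "<"
#: keep values on the boundary.
THRESHOLDS = {
    "standard_nuc_evalue_max": 1e-3,     # e-value < 0.001  (strict)
    "standard_nuc_pident_min": 95.0,     # %ID > 95         (strict)
    "standard_nuc_len_frac_min": 0.5,    # aln > 50% of read length (strict)
    "standard_nuc_bit_min": 50.0,        # bit > 50         (strict)
    "standard_prot_evalue_max": 1e-3,    # e-value < 0.001  (strict)
    "standard_prot_bit_min": 40.0,       # removed if bit < 40  (keep at 40)
    "standard_prot_pident_min": 95.0,    # removed if %ID < 95  (keep at 95)
    "refseq_bit_min": 50.0,              # removed if bit < 50  (keep at 50)
    "recA_bit_min": 50.0,                # counted if bit > 50  (strict)
}

#: Product-title phrases defining RecA database membership (case-sensitive
#: substring match by default).
RECA_KEYWORDS = (
    "recombinase RecA",
    "protein RecA",
    "recombinase A",
    "RecA protein",
)


class FilterError(ValueError):
    """Invalid input to a hit-filtering operation."""


@dataclass(frozen=True)
class Hit:
    """One retained homology hit of a read against a subject set."""

    read_id: str
    subject_id: str
    subject_set: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float
    read_length: int | None = None


@dataclass
class ReadPartition:
    """Disjoint partition of reads: per-standard, community, discarded."""

    standard_reads: dict[str, set[str]] = field(default_factory=dict)
    community_reads: set[str] = field(default_factory=set)
    discarded: dict[str, set[str]] = field(default_factory=dict)

    @property
    def all_standard(self) -> set[str]:
        out: set[str] = set()
        for reads in self.standard_reads.values():
            out |= reads
        return out

    @property
    def all_discarded(self) -> set[str]:
        out: set[str] = set()
        for reads in self.discarded.values():
            out |= reads
        return out

    def standard_of(self, read_id: str) -> str | None:
        for sid, reads in self.standard_reads.items():
            if read_id in reads:
                return sid
        return None


def read_hit_table(path, subject_set: str | None = None) -> pd.DataFrame:
    """Load a 13-column BLAST tabular file (outfmt 6 + qlen).

    ``subject_set`` labels which search the file came from; a 14th column in
    the file takes precedence.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 13:
        df.columns = HIT_COLUMNS[:13]
        df["sset"] = subject_set
    elif df.shape[1] == 14:
        df.columns = HIT_COLUMNS
    else:
        raise FilterError(
            f"expected 13 or 14 tab-separated columns, got {df.shape[1]}"
        )
    df["qseqid"] = df["qseqid"].astype(str)
    df["sseqid"] = df["sseqid"].astype(str)
    return df


def select_top_hit(hits_for_read, min_bit: float | None = None):
    """Best hit among one read's hits: maximal bit score, ties broken by
    lexicographically smallest subject id, then first occurrence.

    Hits below ``min_bit`` are excluded before selection.  Returns ``None``
    when nothing survives (read unannotated).
    """
    best = None
    best_key = None
    for i, h in enumerate(hits_for_read):
        if min_bit is not None and h.bit_score < min_bit:
            continue
        key = (-h.bit_score, h.subject_id, i)
        if best is None or key < best_key:
            best, best_key = h, key
    return best


def select_top_hits(df: pd.DataFrame, min_bit: float | None = None) -> pd.DataFrame:
    """Vectorized top-hit selection: one row per read.

    Same rule as :func:`select_top_hit` applied per ``qseqid``.
    """
    if min_bit is not None:
        df = df[df["bitscore"] >= min_bit]
    if df.empty:
        return df
    order = df.sort_values(
        ["qseqid", "bitscore", "sseqid"],
        ascending=[True, False, True],
        kind="mergesort",  # stable: preserves input order among full ties
    )
    return order.drop_duplicates("qseqid", keep="first")


def identify_standard_reads(
    nuc_hits: pd.DataFrame,
    subject_to_standard: dict[str, str] | None = None,
    all_read_ids=None,
    thresholds: dict | None = None,
) -> ReadPartition:
    """Partition reads into internal-standard reads and community reads.

    A read is a standard read iff its best hit against the standard genomes
    passes all four cutoffs (e-value < 0.001, %ID > 95, alignment length >
    half the read length, bit score > 50); it is assigned to the standard of
    that best hit.  Reads failing any cutoff — and reads with no standard
    hit at all (pass ``all_read_ids``) — are community reads.
    """
    if nuc_hits["qlen"].isna().any():
        raise FilterError("read_length (qlen) required to evaluate length fraction")
    t = thresholds if thresholds is not None else THRESHOLDS
    top = select_top_hits(nuc_hits)
    passing = top[
        (top["evalue"] < t["standard_nuc_evalue_max"])
        & (top["pident"] > t["standard_nuc_pident_min"])
        & (top["length"] > t["standard_nuc_len_frac_min"] * top["qlen"])
        & (top["bitscore"] > t["standard_nuc_bit_min"])
    ]
    part = ReadPartition()
    for _, row in passing.iterrows():
        sid = row["sseqid"]
        if subject_to_standard is not None:
            sid = subject_to_standard[sid]
        part.standard_reads.setdefault(sid, set()).add(row["qseqid"])
    hit_reads = set(nuc_hits["qseqid"])
    std = part.all_standard
    part.community_reads = hit_reads - std
    if all_read_ids is not None:
        part.community_reads |= set(all_read_ids) - std
    return part


def count_standard_protein_reads(
    prot_hits: pd.DataFrame,
    partition: ReadPartition,
    thresholds: dict | None = None,
) -> dict[str, int]:
    """S_s per standard: standard reads whose retained protein hit survives
    the bit ≥ 40 and %ID ≥ 95 filters (strict removal at < 40 / < 95).

    Reads in ``prot_hits`` that are not standard reads in ``partition`` are a
    validation error — the protein search runs on identified standard reads
    only.
    """
    t = thresholds if thresholds is not None else THRESHOLDS
    std_reads = partition.all_standard
    unknown = set(prot_hits["qseqid"]) - std_reads
    if unknown:
        raise FilterError(
            f"{len(unknown)} reads in standard-protein hits are not standard "
            f"reads (e.g. {sorted(unknown)[:3]})"
        )
    top = select_top_hits(prot_hits[prot_hits["evalue"] < t["standard_prot_evalue_max"]])
    kept = top[
        (top["bitscore"] >= t["standard_prot_bit_min"])
        & (top["pident"] >= t["standard_prot_pident_min"])
    ]
    counts = {sid: 0 for sid in partition.standard_reads}
    for rid in kept["qseqid"]:
        counts[partition.standard_of(rid)] += 1
    return counts


def viral_override(bacterial_hit: Hit | None, viral_hit: Hit | None) -> str:
    """Final annotation label for one read given its retained bacterial and
    viral hits: ``"viral"`` iff the viral hit exists and strictly out-scores
    the bacterial one (or there is no bacterial hit); ties keep the bacterial
    annotation; neither hit means ``"unannotated"``.
    """
    if viral_hit is None and bacterial_hit is None:
        return "unannotated"
    if viral_hit is None:
        return "bacterial"
    if bacterial_hit is None:
        return "viral"
    return "viral" if viral_hit.bit_score > bacterial_hit.bit_score else "bacterial"


def arbitrate_annotations(
    refseq_hits: pd.DataFrame, viral_hits: pd.DataFrame
) -> pd.DataFrame:
    """Per-read final annotation over the community protein searches.

    Top hits are selected per read in each set (bacterial hits below 50 bits
    are removed first); the viral hit wins only with a strictly higher bit
    score.  Returns one row per read appearing in either table with columns
    ``qseqid``, ``label`` (bacterial/viral/unannotated), ``sseqid``,
    ``bitscore`` of the winning hit (NaN when unannotated).
    """
    bact = select_top_hits(refseq_hits, min_bit=THRESHOLDS["refseq_bit_min"])
    vir = select_top_hits(viral_hits) if len(viral_hits) else viral_hits
    merged = bact[["qseqid", "sseqid", "bitscore"]].merge(
        vir[["qseqid", "sseqid", "bitscore"]] if len(vir) else
        pd.DataFrame(columns=["qseqid", "sseqid", "bitscore"]),
        on="qseqid", how="outer", suffixes=("_bact", "_vir"),
    )
    all_reads = set(refseq_hits["qseqid"]) | set(viral_hits["qseqid"]) if len(viral_hits) else set(refseq_hits["qseqid"])
    missing = all_reads - set(merged["qseqid"])
    if missing:
        merged = pd.concat(
            [merged, pd.DataFrame({"qseqid": sorted(missing)})], ignore_index=True
        )
    has_b = merged["bitscore_bact"].notna()
    has_v = merged["bitscore_vir"].notna() if "bitscore_vir" in merged else pd.Series(False, index=merged.index)
    viral_wins = has_v & (~has_b | (merged.get("bitscore_vir", np.nan) > merged["bitscore_bact"]))
    label = np.where(viral_wins, "viral", np.where(has_b, "bacterial", "unannotated"))
    out = pd.DataFrame({
        "qseqid": merged["qseqid"],
        "label": label,
        "sseqid": np.where(viral_wins, merged.get("sseqid_vir"), merged["sseqid_bact"]),
        "bitscore": np.where(viral_wins, merged.get("bitscore_vir", np.nan), merged["bitscore_bact"]),
    })
    out.loc[out["label"] == "unannotated", ["sseqid", "bitscore"]] = [None, np.nan]
    return out.reset_index(drop=True)


def build_recA_database_membership(
    protein_titles, case_sensitive: bool = True
) -> set[str]:
    """Protein ids whose free-text title marks a RecA product.

    Membership requires one of the four phrases in :data:`RECA_KEYWORDS` as a
    substring; matching is case-sensitive by default, mirroring the exact
    phrases, with an opt-out for curated databases with uneven capitalization.
    """
    keywords = RECA_KEYWORDS
    if not case_sensitive:
        keywords = tuple(k.lower() for k in keywords)
    members = set()
    for pid, title in protein_titles:
        t = title if case_sensitive else title.lower()
        if any(k in t for k in keywords):
            members.add(pid)
    return members


def _title_is_recA(title, case_sensitive: bool = True) -> bool:
    if not isinstance(title, str):  # missing annotation (None/NaN)
        return False
    keywords = RECA_KEYWORDS if case_sensitive else tuple(k.lower() for k in RECA_KEYWORDS)
    t = title if case_sensitive else title.lower()
    return any(k in t for k in keywords)


def count_recA(
    recA_hits: pd.DataFrame,
    refseq_annotations: pd.DataFrame,
    subject_to_taxon: dict[str, str] | None = None,
    case_sensitive: bool = True,
) -> tuple[pd.Series, dict]:
    """Per-taxon recA read counts with all-protein confirmation.

    A read counts as one recA gene for taxon T iff its top hit against the
    RecA database exceeds 50 bits AND its all-protein annotation confirms a
    RecA product (title keyword match).  The taxon comes from the RecA hit's
    subject; disagreements with the all-protein search's taxon are resolved
    in favor of the RecA search and tallied in the report.

    Parameters
    ----------
    recA_hits
        Hit table of community reads against the RecA database.
    refseq_annotations
        Per-read final community annotation with columns ``qseqid``,
        ``title`` (product title of the all-protein hit) and optionally
        ``taxon``; reads annotated viral should carry a non-RecA title or be
        absent.
    subject_to_taxon
        Maps RecA subject ids to taxa (identity when omitted).

    Returns
    -------
    (counts, report)
        ``counts``: Series indexed by taxon.  ``report``: dict with
        ``n_candidates``, ``n_counted``, ``n_low_bit``, ``n_unconfirmed``,
        ``n_taxon_conflicts``.
    """
    top = select_top_hits(recA_hits)
    ann = refseq_annotations.set_index("qseqid")
    report = {
        "n_candidates": len(top),
        "n_counted": 0,
        "n_low_bit": 0,
        "n_unconfirmed": 0,
        "n_taxon_conflicts": 0,
    }
    counts: dict[str, int] = {}
    for _, row in top.iterrows():
        if not row["bitscore"] > THRESHOLDS["recA_bit_min"]:
            report["n_low_bit"] += 1
            continue
        rid = row["qseqid"]
        title = ann["title"].get(rid) if "title" in ann.columns else None
        if not _title_is_recA(title, case_sensitive):
            report["n_unconfirmed"] += 1
            continue
        taxon = row["sseqid"]
        if subject_to_taxon is not None:
            taxon = subject_to_taxon[taxon]
        if "taxon" in ann.columns:
            other = ann["taxon"].get(rid)
            if other is not None and not pd.isna(other) and other != taxon:
                report["n_taxon_conflicts"] += 1
        counts[taxon] = counts.get(taxon, 0) + 1
        report["n_counted"] += 1
    return pd.Series(counts, dtype=int).sort_index(), report
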