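"""End-to-end glue: hit tables → filtered counts → volumetric abundances.

Chains the arbitration rules of :mod:`quantmg.hit_filtering` with the
spike-in normalization of :mod:`quantmg.quantification` for one sample or a
whole simulated scenario, and provides the count-level shortcut used when
libraries are deep enough that materializing per-read hit tables is
pointless (the simulator's annotated-counts table records exactly what the
hit-table route would count; their equivalence is asserted in the tests).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import hit_filtering as hf
from . import quantification as qt

__all__ = [
    "process_sample_hits",
    "recovery_table",
    "scenario_recovery",
    "scenario_reca_counts",
    "scenario_abundances",
]


def process_sample_hits(
    hit_tables: dict,
    subject_titles: pd.DataFrame,
    standard_ids,
) -> dict:
    """Run the full arbitration on one sample's hit tables.

    Returns a dict with the read partition, per-standard S_s, the final
    community annotations, per-taxon recA counts and the recA report.
    Subject ids follow the ``<taxon>_<protein>`` convention, from which the
    taxon is recovered.
    """
    titles = subject_titles.set_index("sseqid")["title"]
    part = hf.identify_standard_reads(hit_tables["standard_nuc"])
    S_s = (
        hf.count_standard_protein_reads(hit_tables["standard_prot"], part)
        if len(hit_tables["standard_prot"])
        else {}
    )
    ann = hf.arbitrate_annotations(hit_tables["refseq_prot"], hit_tables["viral_prot"])
    ann["title"] = ann["sseqid"].map(titles)
    ann["taxon"] = ann["sseqid"].str.rsplit("_", n=1).str[0]
    # recA subjects follow "<taxon>_recA": strip the suffix to get the taxon
    reca_subjects = {
        s: s.rsplit("_", 1)[0] for s in hit_tables["recA_prot"]["sseqid"].unique()
    }
    reca_counts, report = hf.count_recA(
        hit_tables["recA_prot"], ann, subject_to_taxon=reca_subjects
    )
    return {
        "partition": part,
        "S_s": S_s,
        "annotations": ann,
        "reca_counts": reca_counts,
        "reca_report": report,
    }


def recovery_table(S_s_by_sample: dict, standards) -> pd.DataFrame:
    """Tidy (sample, standard, S_s) frame from per-sample count mappings."""
    rows = []
    for sid, counts in S_s_by_sample.items():
        for s in standards:
            rows.append(
                {
                    "sample_id": sid,
                    "standard_id": s.standard_id,
                    "S_s": int(counts.get(s.standard_id, 0)),
                }
            )
    return pd.DataFrame(rows)


def scenario_recovery(scenario) -> pd.DataFrame:
    """Per-sample standard recoveries straight from the counts tables.

    Every simulated standard read is protein-encoding by construction (the
    sampling weight is S_a × S_p gene molecules), so S_s equals the
    standard's read count.
    """
    rows = []
    for sid, sim in scenario.sims.items():
        std = sim.counts[sim.counts["kind"] == "standard"]
        for _, row in std.iterrows():
            rows.append(
                {
                    "sample_id": sid,
                    "standard_id": row["category_id"],
                    "S_s": int(row["n_reads"]),
                }
            )
    return pd.DataFrame(rows)


def scenario_reca_counts(scenario) -> pd.DataFrame:
    """Tidy per-taxon counted recA reads (post-filter) for every sample."""
    rows = []
    for sid, sim in scenario.sims.items():
        tx = sim.counts[sim.counts["kind"] == "taxon"]
        for _, row in tx.iterrows():
            rows.append(
                {
                    "sample_id": sid,
                    "taxon": row["category_id"],
                    "count": int(row["n_reca_counted"]),
                }
            )
    return pd.DataFrame(rows)


def scenario_abundances(scenario, by_family: bool = True) -> pd.DataFrame:
    """Volumetric genome-equivalent abundance table for a simulated scenario.

    Counts recA per taxon (count level), normalizes by each sample's pooled
    recovery ratio and volume, and optionally bins to families before the
    CI computation.
    """
    counts = scenario_reca_counts(scenario)
    if by_family:
        fam = scenario.taxon_family
        counts = (
            counts.assign(family=counts["taxon"].map(fam))
            .groupby(["sample_id", "family"], as_index=False)["count"]
            .sum()
        )
    recovery = scenario_recovery(scenario)
    volumes = pd.Series(
        {c.sample_id: c.volume_filtered for c in scenario.communities}
    )
    return qt.abundance_table(counts, recovery, scenario.standards, volumes)
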