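"""Annotation arbitration: cutoffs, top hits, viral override, recA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from quantmg import hit_filtering as hf


def make_hits(rows, sset="standard_nuc"):
    """Hit frame from (qseqid, sseqid, pident, length, evalue, bitscore, qlen)."""
    df = pd.DataFrame(
        rows, columns=["qseqid", "sseqid", "pident", "length", "evalue", "bitscore", "qlen"]
    )
    for col, val in [("mismatch", 0), ("gapopen", 0), ("qstart", 1)]:
        df[col] = val
    df["qend"] = df["length"]
    df["sstart"] = 1
    df["send"] = df["length"]
    df["sset"] = sset
    return df[hf.HIT_COLUMNS]


class TestSelectTopHit:
    def hits(self, specs):
        return [
            hf.Hit(read_id="r1", subject_id=s, subject_set="refseq_prot",
                   percent_identity=99.0, alignment_length=50, e_value=1e-10,
                   bit_score=b)
            for s, b in specs
        ]

    def test_max_bit_wins(self):
        best = hf.select_top_hit(self.hits([("x", 60), ("y", 80), ("z", 75)]))
        assert best.bit_score == 80

    def test_tie_broken_by_smallest_subject(self):
        best = hf.select_top_hit(self.hits([("B", 80), ("A", 80)]))
        assert best.subject_id == "A"

    def test_all_below_cutoff_unannotated(self):
        assert hf.select_top_hit(self.hits([("x", 49), ("y", 30)]), min_bit=50) is None

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        rows = []
        for r in range(30):
            for _ in range(rng.integers(1, 5)):
                rows.append(
                    (f"r{r}", f"s{rng.integers(0, 5)}", 99.0, 50, 1e-9,
                     float(rng.integers(30, 120)), 150)
                )
        df = make_hits(rows, "refseq_prot")
        top = hf.select_top_hits(df, min_bit=50).set_index("qseqid")
        for rid, grp in df.groupby("qseqid"):
            hits = [
                hf.Hit(row.qseqid, row.sseqid, "refseq_prot", row.pident,
                       row.length, row.evalue, row.bitscore, row.qlen)
                for row in grp.itertuples()
            ]
            best = hf.select_top_hit(hits, min_bit=50)
            if best is None:
                assert rid not in top.index
            else:
                assert top.loc[rid, "sseqid"] == best.subject_id
                assert top.loc[rid, "bitscore"] == best.bit_score


class TestIdentifyStandardReads:
    def test_all_thresholds_pass(self):
        df = make_hits([("r1", "stdA", 97.0, 100, 1e-5, 120.0, 150)])
        part = hf.identify_standard_reads(df)
        assert part.standard_reads == {"stdA": {"r1"}}

    @pytest.mark.parametrize(
        "pident,length,evalue,bit",
        [
            (95.0, 100, 1e-5, 120.0),   # %ID not strictly > 95
            (97.0, 60, 1e-5, 120.0),    # 40% of read length
            (97.0, 100, 1e-2, 120.0),   # e-value too large
            (97.0, 100, 1e-5, 50.0),    # bit not strictly > 50
            (97.0, 75, 1e-5, 120.0),    # exactly half the read length
        ],
    )
    def test_failing_any_threshold_is_community(self, pident, length, evalue, bit):
        df = make_hits([("r1", "stdA", pident, length, evalue, bit, 150)])
        part = hf.identify_standard_reads(df)
        assert part.standard_reads == {}
        assert part.community_reads == {"r1"}

    def test_missing_read_length_rejected(self):
        df = make_hits([("r1", "stdA", 97.0, 100, 1e-5, 120.0, np.nan)])
        with pytest.raises(hf.FilterError):
            hf.identify_standard_reads(df)

    def test_partition_is_disjoint_and_complete(self):
        rng = np.random.default_rng(1)
        rows = []
        for r in range(200):
            rows.append(
                (f"r{r}", f"std{rng.integers(0, 3)}",
                 float(rng.uniform(90, 100)), int(rng.integers(40, 151)),
                 10.0 ** -rng.integers(1, 20), float(rng.uniform(20, 200)), 150)
            )
        df = make_hits(rows)
        all_reads = {f"r{r}" for r in range(250)}  # 50 reads with no hit
        part = hf.identify_standard_reads(df, all_read_ids=all_reads)
        std = part.all_standard
        assert std | part.community_reads | part.all_discarded == all_reads
        assert not std & part.community_reads
        sets = list(part.standard_reads.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not sets[i] & sets[j]


class TestCountStandardProteinReads:
    def partition(self):
        p = hf.ReadPartition()
        p.standard_reads = {"stdA": {"r1", "r2", "r3"}}
        return p

    @pytest.mark.parametrize(
        "bit,pident,counted",
        [
            (39.0, 99.0, 0),   # removed: bit < 40
            (45.0, 96.0, 1),   # passes both
            (100.0, 94.0, 0),  # removed: %ID < 95
            (40.0, 95.0, 1),   # boundary values are kept
        ],
    )
    def test_protein_filters(self, bit, pident, counted):
        df = make_hits([("r1", "stdA_p1", pident, 40, 1e-8, bit, 150)], "standard_prot")
        assert hf.count_standard_protein_reads(df, self.partition())["stdA"] == counted

    def test_non_standard_read_rejected(self):
        df = make_hits([("rX", "stdA_p1", 99.0, 40, 1e-8, 90.0, 150)], "standard_prot")
        with pytest.raises(hf.FilterError):
            hf.count_standard_protein_reads(df, self.partition())


class TestViralOverride:
    def hit(self, bit):
        return hf.Hit("r1", "s", "viral_prot", 90.0, 40, 1e-9, bit)

    @pytest.mark.parametrize(
        "bact,vir,expected",
        [
            (60.0, 75.0, "viral"),
            (80.0, 75.0, "bacterial"),
            (60.0, 60.0, "bacterial"),  # tie keeps the original annotation
            (None, 75.0, "viral"),
            (60.0, None, "bacterial"),
            (None, None, "unannotated"),
        ],
    )
    def test_rule(self, bact, vir, expected):
        b = self.hit(bact) if bact is not None else None
        v = self.hit(vir) if vir is not None else None
        assert hf.viral_override(b, v) == expected

    def test_arbitrate_matches_scalar_rule(self):
        rng = np.random.default_rng(2)
        bact_rows, vir_rows, expected = [], [], {}
        for r in range(100):
            rid = f"r{r}"
            b = float(rng.uniform(30, 150)) if rng.random() < 0.8 else None
            v = float(rng.uniform(30, 150)) if rng.random() < 0.5 else None
            if b is not None:
                bact_rows.append((rid, "bact_s", 90.0, 40, 1e-9, b, 150))
            if v is not None:
                vir_rows.append((rid, "vir_s", 90.0, 40, 1e-9, v, 150))
            b_eff = b if (b is not None and b >= 50) else None
            bh = self.hit(b_eff) if b_eff is not None else None
            vh = self.hit(v) if v is not None else None
            if b is not None or v is not None:
                expected[rid] = hf.viral_override(bh, vh)
        ann = hf.arbitrate_annotations(
            make_hits(bact_rows, "refseq_prot"), make_hits(vir_rows, "viral_prot")
        ).set_index("qseqid")
        assert ann["label"].to_dict() == expected


class TestRecAKeywords:
    @pytest.mark.parametrize(
        "title,included",
        [
            ("protein RecA [Pelagibacter sp.]", True),
            ("recombinase RecB", False),
            ("DNA recombinase A, partial", True),
            ("RecA protein, partial", True),
            ("recombinase RecA", True),
            ("reca protein", False),            # case-sensitive by default
            ("flagellin", False),
        ],
    )
    def test_membership(self, title, included):
        got = hf.build_recA_database_membership([("p1", title)])
        assert (got == {"p1"}) is included

    def test_case_insensitive_switch(self):
        got = hf.build_recA_database_membership(
            [("p1", "RECA PROTEIN")], case_sensitive=False
        )
        assert got == {"p1"}


class TestCountRecA:
    def annotations(self, title="protein RecA [T1]", taxon="T1"):
        return pd.DataFrame(
            {"qseqid": ["r1"], "title": [title], "taxon": [taxon]}
        )

    def test_counted_with_confirmation(self):
        hits = make_hits([("r1", "T1", 95.0, 40, 1e-9, 120.0, 150)], "recA_prot")
        counts, report = hf.count_recA(hits, self.annotations())
        assert counts.to_dict() == {"T1": 1}
        assert report["n_counted"] == 1

    def test_bit_exactly_50_not_counted(self):
        hits = make_hits([("r1", "T1", 95.0, 40, 1e-9, 50.0, 150)], "recA_prot")
        counts, report = hf.count_recA(hits, self.annotations())
        assert counts.empty
        assert report["n_low_bit"] == 1

    def test_unconfirmed_title_not_counted(self):
        hits = make_hits([("r1", "T1", 95.0, 40, 1e-9, 120.0, 150)], "recA_prot")
        counts, report = hf.count_recA(hits, self.annotations(title="flagellin"))
        assert counts.empty
        assert report["n_unconfirmed"] == 1

    def test_taxon_conflict_goes_to_recA_search(self):
        hits = make_hits([("r1", "T1", 95.0, 40, 1e-9, 120.0, 150)], "recA_prot")
        counts, report = hf.count_recA(
            hits, self.annotations(taxon="T2")
        )
        assert counts.to_dict() == {"T1": 1}
        assert report["n_taxon_conflicts"] == 1


class TestMonotonicity:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 20),                  # read index
                st.floats(80, 100),                  # pident
                st.integers(30, 150),                # aln length
                st.floats(20, 150),                  # bitscore
            ),
            min_size=1,
            max_size=60,
        ),
        st.floats(40, 100),
    )
    def test_raising_bit_threshold_never_retains_more(self, rows, higher_bit):
        """Raising any cutoff can only shrink the set of standard reads."""
        df = make_hits(
            [(f"r{i}", "stdA", p, ln, 1e-9, b, 150) for i, p, ln, b in rows]
        )
        base = hf.THRESHOLDS.copy()
        stricter = base.copy()
        stricter["standard_nuc_bit_min"] = max(base["standard_nuc_bit_min"], higher_bit)
        stricter["standard_nuc_pident_min"] = 97.0
        n_base = len(hf.identify_standard_reads(df, thresholds=base).all_standard)
        n_strict = len(hf.identify_standard_reads(df, thresholds=stricter).all_standard)
        assert n_strict <= n_base


def naive_standard_partition(df):
    """Row-by-row reference implementation of standard-read identification."""
    best = {}
    for row in df.itertuples():
        key = row.qseqid
        cand = best.get(key)
        if (
            cand is None
            or row.bitscore > cand.bitscore
            or (row.bitscore == cand.bitscore and row.sseqid < cand.sseqid)
        ):
            best[key] = row
    standard, community = {}, set()
    for rid, row in best.items():
        if (
            row.evalue < 1e-3
            and row.pident > 95
            and row.length > 0.5 * row.qlen
            and row.bitscore > 50
        ):
            standard.setdefault(row.sseqid, set()).add(rid)
        else:
            community.add(rid)
    return standard, community


class TestOracleEquivalence:
    def test_filtering_matches_naive_reimplementation(self):
        rng = np.random.default_rng(5)
        rows = []
        for r in range(300):
            for _ in range(rng.integers(1, 4)):
                rows.append(
                    (f"r{r:03d}", f"std{rng.integers(0, 3)}",
                     float(rng.uniform(90, 100)), int(rng.integers(40, 151)),
                     10.0 ** -float(rng.uniform(0, 20)),
                     float(rng.choice([40, 50, 50, 60, 80, 120])), 150)
                )
        df = make_hits(rows)
        part = hf.identify_standard_reads(df)
        std_naive, comm_naive = naive_standard_partition(df)
        assert part.standard_reads == std_naive
        assert part.community_reads == comm_naive


class TestSimulatedDualHits:
    def test_viral_fraction_matches_simulated_probability(self, small_scenario):
        """With iid bacterial/viral bit scores the viral hit wins half the
        dual-hit reads; the arbitration recovers that fraction."""
        n_dual = n_viral = 0
        for sim in small_scenario.sims.values():
            tx = sim.counts[sim.counts["kind"] == "taxon"]
            n_dual += tx["n_dual"].sum()
            n_viral += tx["n_dual_viral"].sum()
        assert n_dual > 100
        p_hat = n_viral / n_dual
        sd = np.sqrt(0.25 / n_dual)
        assert abs(p_hat - 0.5) < 3 * sd
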