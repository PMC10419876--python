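"""Sliding-window DMR calling, merging, direction, gene association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylink.dmr import (
    DmrParams,
    aggregate_dmgs,
    associate_dmrs,
    build_features,
    call_dmrs,
    classify_direction,
    fisher_twosided,
    promoter_interval,
)


def counts_table(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "sample", "m", "u"]
    )


def strong_signal_counts():
    """One window's worth of CG sites: case pooled 60/40, control 5/95."""
    rows = []
    case = [(6, 4)] * 10                      # 10 sites x (m=6, u=4)
    control = [(1, 9)] * 5 + [(0, 10)] * 5    # pooled 5/95
    for i, (m, u) in enumerate(case):
        rows.append(("chr1", i * 4, "+", "CG", "case_1", m, u))
    for i, (m, u) in enumerate(control):
        rows.append(("chr1", i * 4, "+", "CG", "ctrl_1", m, u))
    return counts_table(rows)


class TestFisher:
    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 80, 4))
            assert fisher_twosided(a, b, c, d) == pytest.approx(
                stats.fisher_exact([[a, b], [c, d]])[1], rel=1e-7, abs=1e-300
            )

    def test_strong_table_enumeration(self):
        p = fisher_twosided(60, 40, 5, 95)
        assert p < 1e-15
        assert p == pytest.approx(stats.fisher_exact([[60, 40], [5, 95]])[1], rel=1e-7)


class TestCallDmrs:
    LENGTHS = {"chr1": 100}

    def test_identical_conditions_yield_no_dmrs(self):
        rows = []
        for i in range(10):
            rows.append(("chr1", i * 4, "+", "CG", "case_1", 5, 5))
            rows.append(("chr1", i * 4, "+", "CG", "ctrl_1", 5, 5))
        dmrs = call_dmrs(counts_table(rows), ["case_1"], ["ctrl_1"], self.LENGTHS)
        assert dmrs.empty

    def test_single_strong_hyper_dmr(self):
        dmrs = call_dmrs(strong_signal_counts(), ["case_1"], ["ctrl_1"], self.LENGTHS)
        assert len(dmrs) == 1
        d = dmrs.iloc[0]
        assert d["direction"] == "hyper"
        assert d["delta"] == pytest.approx(0.55)
        assert d["p"] < 1e-15
        assert d["q"] < 0.05
        assert d["ml_case"] == pytest.approx(0.60)
        assert d["ml_control"] == pytest.approx(0.05)

    def test_label_swap_flips_direction_and_negates_delta(self):
        counts = strong_signal_counts()
        fwd = call_dmrs(counts, ["case_1"], ["ctrl_1"], self.LENGTHS)
        rev = call_dmrs(counts, ["ctrl_1"], ["case_1"], self.LENGTHS)
        assert len(fwd) == len(rev) == 1
        assert rev["delta"].iloc[0] == pytest.approx(-fwd["delta"].iloc[0])
        assert rev["p"].iloc[0] == pytest.approx(fwd["p"].iloc[0], rel=1e-9)
        assert {fwd["direction"].iloc[0], rev["direction"].iloc[0]} == {"hyper", "hypo"}

    def test_no_covered_windows_errors(self):
        rows = [("chr1", 0, "+", "CG", "case_1", 5, 5)]  # control never covered
        with pytest.raises(ValueError, match="covered"):
            call_dmrs(counts_table(rows), ["case_1"], ["ctrl_1"], self.LENGTHS)

    def test_empty_condition_errors_and_single_sample_warns(self, caplog):
        with pytest.raises(ValueError, match="at least one sample"):
            call_dmrs(strong_signal_counts(), [], ["ctrl_1"], self.LENGTHS)
        with caplog.at_level("WARNING"):
            call_dmrs(strong_signal_counts(), ["case_1"], ["ctrl_1"], self.LENGTHS)
        assert any("no replication" in rec.message for rec in caplog.records)

    def test_merging_never_joins_opposite_directions(self):
        rows = []
        # [0, 200): case hyper; [200, 400): case hypo; dense CG sites
        for pos in range(0, 400, 5):
            hyper = pos < 200
            rows.append(("chr1", pos, "+", "CG", "case_1", 18 if hyper else 2, 2 if hyper else 18))
            rows.append(("chr1", pos, "+", "CG", "ctrl_1", 2 if hyper else 18, 18 if hyper else 2))
        dmrs = call_dmrs(counts_table(rows), ["case_1"], ["ctrl_1"], {"chr1": 400})
        assert set(dmrs["direction"]) == {"hyper", "hypo"}
        # no single merged region spans both planted cores
        for d in dmrs.itertuples():
            assert not (d.start <= 50 and d.end >= 350)

    def test_hyper_plus_hypo_equals_total(self, pipeline_cache):
        _, dmrs = pipeline_cache("long_term", 1)
        n_hyper = (dmrs["direction"] == "hyper").sum()
        n_hypo = (dmrs["direction"] == "hypo").sum()
        assert n_hyper + n_hypo == len(dmrs)
        for _, sub in dmrs.groupby("context"):
            assert ((sub["direction"] == "hyper").sum()
                    + (sub["direction"] == "hypo").sum()) == len(sub)

    def test_context_exclusive_and_q_contract(self, pipeline_cache):
        _, dmrs = pipeline_cache("long_term", 1)
        assert not dmrs.duplicated(subset=["chrom", "start", "end", "context"]).any()
        assert (dmrs["q"] < 0.05).all()
        assert (dmrs["delta"].abs() >= 0.1).all()


class TestDirection:
    def test_table_like_values(self):
        assert classify_direction(0.33) == "hyper"
        assert classify_direction(-0.36) == "hypo"

    def test_zero_delta_rejected(self):
        with pytest.raises(ValueError):
            classify_direction(0.0)


@pytest.fixture()
def toy_annotation():
    genes = pd.DataFrame(
        [
            {"gene_id": "gA", "chrom": "chr1", "start": 1500, "end": 3100, "strand": "+"},
        ]
    )
    subfeatures = pd.DataFrame(
        [
            {"gene_id": "gA", "chrom": "chr1", "kind": "five_prime_UTR",
             "start": 1500, "end": 1650, "strand": "+"},
            {"gene_id": "gA", "chrom": "chr1", "kind": "exon",
             "start": 1650, "end": 2000, "strand": "+"},
            {"gene_id": "gA", "chrom": "chr1", "kind": "exon",
             "start": 2400, "end": 2950, "strand": "+"},
            {"gene_id": "gA", "chrom": "chr1", "kind": "three_prime_UTR",
             "start": 2950, "end": 3100, "strand": "+"},
        ]
    )
    return genes, subfeatures


def dmr_row(start, end, context="CG", direction="hyper", delta=0.3):
    return pd.DataFrame(
        [{
            "dmr_id": f"chr1:{start}-{end}:{context}", "chrom": "chr1",
            "start": start, "end": end, "context": context,
            "ml_case": 0.5, "ml_control": 0.2, "delta": delta,
            "p": 1e-9, "q": 1e-8, "direction": direction,
        }]
    )


class TestAssociation:
    def test_promoter_overlap(self, toy_annotation):
        genes, subfeatures = toy_annotation
        features = build_features(genes, subfeatures, {"chr1": 10_000}, promoter_length=2000)
        links = associate_dmrs(dmr_row(1000, 1200), features)
        assert list(links["gene_id"]) == ["gA"]
        assert links["feature"].iloc[0] == "promoter"

    def test_no_overlap_no_link(self, toy_annotation):
        genes, subfeatures = toy_annotation
        features = build_features(genes, subfeatures, {"chr1": 10_000}, promoter_length=2000)
        links = associate_dmrs(dmr_row(5000, 5200), features)
        assert links.empty

    def test_exon_intron_junction_records_both(self, toy_annotation):
        genes, subfeatures = toy_annotation
        features = build_features(genes, subfeatures, {"chr1": 10_000}, promoter_length=2000)
        links = associate_dmrs(dmr_row(1950, 2100), features)  # exon1/intron junction
        assert set(links["features"].iloc[0].split(";")) == {"exon", "intron"}

    def test_intron_derivation_tiles_gene_body(self, toy_annotation):
        genes, subfeatures = toy_annotation
        features = build_features(genes, subfeatures, {"chr1": 10_000}, promoter_length=2000)
        body = features[(features["gene_id"] == "gA") & (features["kind"] != "promoter")]
        assert (body["end"] - body["start"]).sum() == 3100 - 1500
        introns = body[body["kind"] == "intron"]
        assert list(zip(introns["start"], introns["end"])) == [(2000, 2400)]

    def test_promoter_interval_strand_aware_and_truncated(self):
        assert promoter_interval(1500, 3100, "+", 2000, 10_000) == (0, 1500)
        assert promoter_interval(1500, 3100, "-", 2000, 4000) == (3100, 4000)

    def test_gene_with_both_directions_in_both_tallies(self, toy_annotation):
        genes, subfeatures = toy_annotation
        features = build_features(genes, subfeatures, {"chr1": 10_000}, promoter_length=2000)
        dmrs = pd.concat(
            [dmr_row(1000, 1200), dmr_row(2500, 2700, direction="hypo", delta=-0.3)],
            ignore_index=True,
        )
        links = associate_dmrs(dmrs, features)
        dmgs = aggregate_dmgs(links)
        assert dmgs["directions"].iloc[0] == "hyper;hypo"
        assert dmgs["n_dmrs"].iloc[0] == 2
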