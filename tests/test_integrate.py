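"""DMG-DEG overlap, quadrant tallies, distributions, correlation, report."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylink.integrate import (
    classify_quadrants,
    correlate,
    distribution_by,
    gene_report,
    overlap_dmg_deg,
    scatter_pairs,
)

from tests._oracles import spearman_oracle


def make_links(genes, feature="promoter", context="CG", direction="hyper", delta=0.3):
    rows = []
    for i, g in enumerate(genes):
        rows.append(
            {
                "gene_id": g, "dmr_id": f"chr1:{i * 1000}-{i * 1000 + 200}:{context}",
                "chrom": "chr1", "start": i * 1000, "end": i * 1000 + 200,
                "context": context, "direction": direction, "delta": delta,
                "feature": feature, "features": feature,
            }
        )
    return pd.DataFrame(rows)


def make_degs(genes, status="up", log2fc=2.0):
    return pd.DataFrame(
        {
            "gene_id": list(genes),
            "log2fc": log2fc,
            "p": 1e-4,
            "q": 1e-3,
            "de_status": status,
        }
    )


class TestOverlap:
    def test_disjoint_sets_empty(self):
        records = overlap_dmg_deg(make_links(["a", "b"]), make_degs(["c", "d"]))
        assert records.empty

    def test_set_algebra_example(self):
        records = overlap_dmg_deg(make_links(["a", "b", "c"]), make_degs(["b", "c", "d"]))
        assert sorted(records["gene_id"]) == ["b", "c"]

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(60)]
        dmg_genes = list(rng.choice(genes, 40, replace=False))
        # 11 overlapping + 19 DEG-only
        deg_genes = dmg_genes[:11] + [g for g in genes if g not in dmg_genes][:19]
        records = overlap_dmg_deg(make_links(dmg_genes), make_degs(deg_genes))
        assert set(records["gene_id"]) == set(dmg_genes) & set(deg_genes)
        assert records["gene_id"].nunique() == 11

    def test_non_deg_genes_excluded(self):
        degs = pd.concat(
            [make_degs(["a"]), make_degs(["b"], status="none")], ignore_index=True
        )
        records = overlap_dmg_deg(make_links(["a", "b"]), degs)
        assert list(records["gene_id"]) == ["a"]

    def test_duplicate_deg_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            overlap_dmg_deg(make_links(["a"]), make_degs(["a", "a"]))


class TestQuadrants:
    def test_single_hyper_up(self):
        records = overlap_dmg_deg(make_links(["a"]), make_degs(["a"]))
        tally = classify_quadrants(records)
        assert tally.loc["hyper", "up"] == 1
        assert tally.to_numpy().sum() == 1

    def test_gene_with_both_directions_counts_twice(self):
        links = pd.concat(
            [make_links(["a"]), make_links(["a"], direction="hypo", delta=-0.2)],
            ignore_index=True,
        )
        links["dmr_id"] = ["d1", "d2"]
        records = overlap_dmg_deg(links, make_degs(["a"]))
        tally = classify_quadrants(records)
        assert tally.loc["hyper", "up"] == 1
        assert tally.loc["hypo", "up"] == 1
        assert tally.to_numpy().sum() == 2  # exceeds the 1-gene record count

    def test_random_fixture_matches_enumeration(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(10):
            rows.append(
                {
                    "gene_id": f"g{i % 6}", "dmr_id": f"d{i}", "chrom": "chr1",
                    "start": i, "end": i + 1, "context": "CG",
                    "direction": rng.choice(["hyper", "hypo"]),
                    "delta": 0.2, "feature": "exon", "features": "exon",
                }
            )
        links = pd.DataFrame(rows)
        degs = make_degs(
            [f"g{i}" for i in range(6)],
            status=[rng.choice(["up", "down"]) for _ in range(6)],
        )
        records = overlap_dmg_deg(links, degs)
        tally = classify_quadrants(records)
        expected = {}
        for (gene, direction), sub in records.groupby(["gene_id", "direction"]):
            key = (direction, sub["de_status"].iloc[0])
            expected[key] = expected.get(key, 0) + 1
        for (direction, status), count in expected.items():
            assert tally.loc[direction, status] == count
        assert tally.to_numpy().sum() == sum(expected.values())


class TestDistribution:
    def test_all_promoter(self):
        records = overlap_dmg_deg(make_links(["a", "b"]), make_degs(["a", "b"]))
        dist = distribution_by(records, "feature").set_index("feature")
        assert dist.loc["promoter", "proportion"] == 1.0

    def test_proportions_from_link_counts(self):
        links = pd.concat(
            [
                make_links(["a", "b", "c"], feature="promoter"),
                make_links(["d", "e", "f"], feature="exon"),
                make_links(["g", "h"], feature="intron"),
            ],
            ignore_index=True,
        )
        links["dmr_id"] = [f"d{i}" for i in range(len(links))]
        degs = make_degs(list("abcdefgh"))
        dist = distribution_by(overlap_dmg_deg(links, degs), "feature").set_index("feature")
        assert dist.loc["promoter", "proportion"] == pytest.approx(3 / 8)
        assert dist.loc["exon", "proportion"] == pytest.approx(3 / 8)
        assert dist.loc["intron", "proportion"] == pytest.approx(2 / 8)

    def test_proportions_sum_to_one(self):
        links = make_links(list("abc"), feature="promoter")
        links.loc[1, "features"] = "exon;intron"  # multi-feature link counts per kind
        dist = distribution_by(overlap_dmg_deg(links, make_degs(list("abc"))), "feature")
        assert dist["proportion"].sum() == pytest.approx(1.0)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            distribution_by(pd.DataFrame(columns=["context"]), "context")


class TestCorrelate:
    def pairs(self, xy, feature="promoter", context="CG"):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(xy))],
                "delta": [p[0] for p in xy],
                "log2fc": [p[1] for p in xy],
                "feature": feature,
                "context": context,
            }
        )

    def test_exact_linear_relationship(self):
        out = correlate(self.pairs([(0.1, 1.0), (0.2, 2.0), (0.3, 3.0)]))
        row = out[out["stratum"] == "overall"].iloc[0]
        assert row["r2"] == pytest.approx(1.0)
        assert row["spearman_rho"] == pytest.approx(1.0)

    def test_rank_oracle_with_swapped_neighbours(self):
        xy = [(1, 2), (2, 1), (3, 4), (4, 3)]
        out = correlate(self.pairs(xy))
        rho = out.loc[out["stratum"] == "overall", "spearman_rho"].iloc[0]
        assert rho == pytest.approx(spearman_oracle([p[0] for p in xy], [p[1] for p in xy]))
        assert rho == pytest.approx(0.6)

    def test_constant_vector_undefined(self):
        out = correlate(self.pairs([(0.5, 1.0), (0.5, 2.0), (0.5, 3.0)]))
        assert np.isnan(out.loc[out["stratum"] == "overall", "r2"].iloc[0])

    def test_small_strata_not_reported(self):
        out = correlate(self.pairs([(0.1, 1.0), (0.2, 2.0)]))
        assert out.empty

    def test_order_and_affine_invariance(self):
        rng = np.random.default_rng(2)
        xy = list(zip(rng.normal(size=20), rng.normal(size=20)))
        base = correlate(self.pairs(xy)).set_index("stratum")
        shuffled = correlate(self.pairs([xy[i] for i in rng.permutation(20)])).set_index("stratum")
        assert base.loc["overall", "r2"] == pytest.approx(shuffled.loc["overall", "r2"])
        scaled = correlate(self.pairs([(3 * x - 1, 0.5 * y + 4) for x, y in xy])).set_index("stratum")
        assert base.loc["overall", "r2"] == pytest.approx(scaled.loc["overall", "r2"])


class TestScatterPairs:
    def test_largest_absolute_delta_link_wins(self):
        links = pd.concat(
            [make_links(["a"], delta=0.2), make_links(["a"], direction="hypo", delta=-0.6)],
            ignore_index=True,
        )
        links["dmr_id"] = ["d1", "d2"]
        pairs = scatter_pairs(links, make_degs(["a"]), gene_set="records")
        assert pairs["delta"].iloc[0] == pytest.approx(-0.6)

    def test_linked_mode_includes_non_degs(self):
        degs = pd.concat([make_degs(["a"]), make_degs(["b"], status="none", log2fc=0.1)],
                         ignore_index=True)
        links = make_links(["a", "b"])
        assert len(scatter_pairs(links, degs, gene_set="records")) == 1
        assert len(scatter_pairs(links, degs, gene_set="linked")) == 2


class TestGeneReport:
    def test_one_row_per_link_and_roundtrip(self, tmp_path):
        links = pd.concat([make_links(["a"]), make_links(["a", "b"])], ignore_index=True)
        links["dmr_id"] = ["d1", "d2", "d3"]
        records = overlap_dmg_deg(links, make_degs(["a", "b"]))
        report = gene_report(records, ["a", "b"])
        assert (report["gene_id"] == "a").sum() == 2
        assert (report["start"] == records.sort_values(["gene_id", "start"])["start"].to_numpy() + 1).all()
        path = tmp_path / "report.tsv"
        report.to_csv(path, sep="\t", index=False)
        again = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(report, again)

    def test_unknown_gene_rejected(self):
        records = overlap_dmg_deg(make_links(["a"]), make_degs(["a"]))
        with pytest.raises(ValueError, match="zzz"):
            gene_report(records, ["zzz"])
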