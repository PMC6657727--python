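"""Window metrics, state categories, threshold machinery, gene correlations."""

import numpy as np
import pandas as pd
import pytest

from tnscape import stats
from tnscape.genome import FEATURE_COLUMNS, AnnotationSet, Genome


def make_genome(length=1000):
    return Genome(["chrI"], {"chrI": "A" * length})


def sites_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])


class TestWindowMetrics:
    def test_unique_and_mean_count_arithmetic(self):
        genome = make_genome(100)
        sites = sites_df(
            [("chrI", 3, "+", 2), ("chrI", 40, "+", 1), ("chrI", 77, "-", 1)]
        )
        win = stats.window_metrics(genome, sites, None)
        assert len(win) == 1
        assert win["unique"].iloc[0] == 3
        assert win["mean_count"].iloc[0] == pytest.approx(0.04)

    def test_mean_state_missing_below_mappable_cutoff(self):
        genome = make_genome(200)
        states = {"chrI": np.ones(200, dtype=int)}
        mask = {"chrI": np.ones(200)}
        mask["chrI"][:6] = 0  # first window 94% mappable
        states["chrI"][:6] = 0
        win = stats.window_metrics(genome, sites_df([]), states, mask)
        assert np.isnan(win["mean_state"].iloc[0])
        assert win["mean_state"].iloc[1] == 1.0

    def test_trailing_partial_window_dropped(self):
        genome = make_genome(250)
        win = stats.window_metrics(genome, sites_df([]), None)
        assert len(win) == 2

    def test_matches_bruteforce_on_random_windows(self):
        rng = np.random.default_rng(0)
        length = 5000
        genome = make_genome(length)
        pos = np.sort(rng.choice(length, size=300, replace=False))
        counts = rng.integers(1, 5, size=300)
        sites = sites_df([("chrI", int(p), "+", int(c)) for p, c in zip(pos, counts)])
        states = {"chrI": rng.integers(1, 6, size=length)}
        cons = {"chrI": rng.normal(size=length)}
        win = stats.window_metrics(genome, sites, states, None, cons)
        for w in rng.choice(len(win), size=50, replace=False):
            lo, hi = w * 100, (w + 1) * 100
            inside = (pos >= lo) & (pos < hi)
            assert win["unique"].iloc[w] == inside.sum()
            assert win["mean_count"].iloc[w] == pytest.approx(
                counts[inside].sum() / 100
            )
            assert win["mean_state"].iloc[w] == pytest.approx(
                states["chrI"][lo:hi].mean()
            )
            assert win["mean_conservation"].iloc[w] == pytest.approx(
                cons["chrI"][lo:hi].mean()
            )

    def test_class_requires_full_window_coverage(self):
        genome = make_genome(200)
        codes = {"chrI": np.array([0] * 100 + [0] * 50 + [4] * 50, dtype=np.int8)}
        win = stats.window_metrics(genome, sites_df([]), None, class_codes=codes)
        assert win["class"].tolist() == ["eCDS", None]


class TestStateCategory:
    @pytest.mark.parametrize(
        "mean,expected",
        [
            (1.0, 1), (2.0, 2), (3.2, 3), (2.6, 3), (1.7, 0), (2.5, 0),
            (3.5, 0), (4.4, 4), (5.49, 5), (1.01, 0), (float("nan"), 0),
        ],
    )
    def test_examples(self, mean, expected):
        assert stats.state_category(mean) == expected

    def test_partition_no_double_assignment(self):
        grid = np.round(np.arange(1.0, 5.5, 0.01), 10)
        cats = stats.state_category(grid)
        # vectorised and scalar agree, and each mean maps to one category
        for m, c in zip(grid[::7], cats[::7]):
            assert stats.state_category(float(m)) == c


class TestAnnotationClassSummary:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=200)
        win = pd.DataFrame({
            "class": ["eCDS"] * 100 + ["nCDS"] * 100,
            "metric": np.concatenate([vals[:100], vals[:100]]),
        })
        _, tests = stats.annotation_class_summary(win, "metric")
        assert tests["p"].iloc[0] > 0.9

    def test_small_class_skipped_with_note(self):
        win = pd.DataFrame({
            "class": ["eCDS"] * 10 + ["nCDS"],
            "metric": np.arange(11.0),
        })
        _, tests = stats.annotation_class_summary(win, "metric")
        assert "skipped" in tests["note"].iloc[0]

    def test_designed_depletion_ordering_recovered(self):
        rng = np.random.default_rng(2)
        frames = []
        for cls, mu in [("eCDS", 1), ("nCDS", 3), ("UTR_intron", 5), ("unannotated", 8)]:
            frames.append(pd.DataFrame({
                "class": cls, "metric": rng.poisson(mu, size=120).astype(float)
            }))
        win = pd.concat(frames, ignore_index=True)
        summary, tests = stats.annotation_class_summary(win, "metric")
        medians = summary.set_index("class")["median"]
        assert medians["eCDS"] < medians["nCDS"] < medians["unannotated"]
        assert (tests["p"] < 0.01).all()


class TestThreshold:
    def test_percentile_example(self):
        assert stats.percentile_linear(np.arange(20), 95) == pytest.approx(18.05)

    def test_percentile_matches_closed_form_small_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            v = np.sort(rng.normal(size=int(rng.integers(2, 12))))
            pct = float(rng.uniform(0, 100))
            h = (len(v) - 1) * pct / 100
            lo = int(np.floor(h))
            expected = v[lo] + (h - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])
            assert stats.percentile_linear(v, pct) == pytest.approx(expected)

    def test_threshold_and_fractions(self):
        win = pd.DataFrame({
            "class": ["eCDS"] * 20 + ["unannotated"] * 30,
            "unique": list(range(20)) + [50.0] * 30,
            "mean_conservation": [0.5] * 20 + [0.1] * 30,
        })
        result = stats.model_free_threshold(win)
        assert result["threshold"] == pytest.approx(18.05)
        # 19 of 20 essential windows below; no unannotated window below
        assert result["fraction_below"] == pytest.approx(19 / 50)
        assert result["per_class_fraction_below"]["eCDS"] == pytest.approx(0.95)
        assert result["per_class_fraction_below"]["unannotated"] == 0.0

    def test_empty_site_table_all_below_positive_threshold(self):
        # degenerate: no insertions anywhere; any positive threshold puts
        # every window below it
        win = pd.DataFrame({
            "class": ["eCDS"] * 5 + ["unannotated"] * 5,
            "unique": [0.0] * 10, "mean_conservation": [0.1] * 10,
        })
        result = stats.model_free_threshold(win, threshold=1.0)
        assert result["fraction_below"] == 1.0

    def test_no_essential_windows_errors(self):
        win = pd.DataFrame({"class": ["nCDS"], "unique": [1.0],
                            "mean_conservation": [0.1]})
        with pytest.raises(ValueError, match="essential"):
            stats.model_free_threshold(win)


class TestGeneMetrics:
    def _world(self):
        feats = pd.DataFrame(
            [
                ("chrI", 0, 100, "+", "CDS", "g1"),
                ("chrI", 200, 300, "+", "CDS", "g2"),
                ("chrI", 400, 500, "+", "CDS", "g3"),
            ],
            columns=FEATURE_COLUMNS,
        )
        annotations = AnnotationSet(
            feats, {"g1": "essential", "g2": "nonessential", "g3": "nonessential"}
        )
        states = {"chrI": np.concatenate([
            np.ones(100, int), np.zeros(100, int), np.full(100, 2),
            np.zeros(100, int), np.full(100, 3),
        ])}
        sites = sites_df(
            [("chrI", 10, "+", 1), ("chrI", 250, "+", 1), ("chrI", 260, "-", 2),
             ("chrI", 450, "+", 1), ("chrI", 455, "+", 1), ("chrI", 460, "+", 1)]
        )
        return annotations, sites, states

    def test_per_gene_metrics(self):
        annotations, sites, states = self._world()
        metrics = stats.gene_metrics(annotations, sites, states)
        by_gene = metrics.set_index("gene_id")
        assert by_gene.loc["g1", "inserts_per_nt"] == pytest.approx(0.01)
        assert by_gene.loc["g2", "inserts_per_nt"] == pytest.approx(0.02)
        assert by_gene.loc["g3", "mean_state"] == 3.0

    def test_fitness_identical_to_metric_gives_r_one(self):
        annotations, sites, states = self._world()
        metrics = stats.gene_metrics(annotations, sites, states)
        fitness = metrics[["gene_id", "inserts_per_nt"]].rename(
            columns={"inserts_per_nt": "fitness"}
        )
        _, report = stats.gene_metrics_and_correlation(
            annotations, sites, states, fitness
        )
        assert report["inserts_per_nt"]["pearson_r"] == pytest.approx(1.0)

    def test_zero_mappable_gene_excluded(self):
        annotations, sites, states = self._world()
        mask = {"chrI": np.ones(500)}
        mask["chrI"][0:100] = 0  # g1 fully unmappable
        metrics = stats.gene_metrics(annotations, sites, states, mask)
        assert metrics.set_index("gene_id").loc["g1", "excluded"]

    def test_too_few_shared_genes_errors(self):
        annotations, sites, states = self._world()
        fitness = pd.DataFrame({"gene_id": ["g1"], "fitness": [1.0]})
        with pytest.raises(ValueError, match="genes"):
            stats.gene_metrics_and_correlation(annotations, sites, states, fitness)

    def test_noisy_monotone_fitness_recovers_positive_sign(self):
        rng = np.random.default_rng(4)
        n = 60
        feats, ess, states_arr, sites_rows = [], {}, [], []
        for g in range(n):
            start = g * 200
            feats.append(("chrI", start, start + 100, "+", "CDS", f"g{g}"))
            ess[f"g{g}"] = "nonessential"
            depletion = rng.uniform(0.0, 1.0)
            states_arr.append(np.full(100, 1 + round(3 * depletion)))
            states_arr.append(np.zeros(100, int))
            for p in range(start, start + 100):
                if rng.random() < 0.05 + 0.3 * depletion:
                    sites_rows.append(("chrI", p, "+", 1))
        annotations = AnnotationSet(
            pd.DataFrame(feats, columns=FEATURE_COLUMNS), ess
        )
        states = {"chrI": np.concatenate(states_arr)}
        sites = sites_df(sites_rows)
        metrics = stats.gene_metrics(annotations, sites, states)
        fitness = pd.DataFrame({
            "gene_id": metrics["gene_id"],
            "fitness": metrics["mean_state"] + rng.normal(scale=0.5, size=n),
        })
        _, report = stats.gene_metrics_and_correlation(
            annotations, sites, states, fitness
        )
        assert report["mean_state"]["pearson_r"] > 0.3
        assert report["inserts_per_nt"]["pearson_r"] > 0.3
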