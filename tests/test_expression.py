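"""Contrast statistics, BH adjustment and the eight-way classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrcistrome.expression import (
    RESPONSE_TYPES,
    ClassifierThresholds,
    ExpressionMatrix,
    bh_adjust,
    classify_all,
    classify_gene,
    contrast_stats,
    response_type_proportions,
    switch_ratio_summary,
)
from nrcistrome.simulate import simulate_expression, simulate_genome

from conftest import small_sim_config


def _matrix(rows, reps=3):
    """Build an ExpressionMatrix from {gene: {(genotype,treatment): [values]}}."""
    samples, design = [], []
    some_gene = next(iter(rows.values()))
    for genotype, treatment in some_gene:
        for r in range(1, len(some_gene[(genotype, treatment)]) + 1):
            name = f"{genotype}_{treatment}_r{r}"
            samples.append(name)
            design.append(
                {"sample": name, "genotype": genotype, "treatment": treatment, "replicate": r}
            )
    data = {}
    for gene, conds in rows.items():
        row = []
        for genotype, treatment in some_gene:
            row.extend(conds[(genotype, treatment)])
        data[gene] = row
    values = pd.DataFrame(data, index=samples).T
    values.columns = samples
    return ExpressionMatrix(values, pd.DataFrame(design))


FULL_DESIGN = [("wt", "vehicle"), ("wt", "ligand"), ("null", "vehicle"), ("null", "ligand")]


def _full_matrix(gene_rows):
    """gene_rows: {gene: (wt_veh, wt_lig, null_veh, null_lig) replicate lists}"""
    return _matrix(
        {
            g: dict(zip(FULL_DESIGN, cond_lists))
            for g, cond_lists in gene_rows.items()
        }
    )


class TestContrastStats:
    def test_identical_groups_are_null(self):
        mat = _full_matrix({"g": ([1.0, 1.2, 0.8], [1.0, 1.2, 0.8], [1, 1, 1], [1, 1, 1])})
        res = contrast_stats(mat, ("wt", "ligand"), ("wt", "vehicle"))
        assert res.at["g", "fold_change"] == pytest.approx(1.0)
        assert res.at["g", "p"] == pytest.approx(1.0)

    def test_hand_computed_contrast(self):
        # A=(1.0,1.2,0.8) vs B=(2.0,2.2,1.8): delta=-1, FC=2, direction down
        mat = _full_matrix({"g": ([2.0, 2.2, 1.8], [1.0, 1.2, 0.8], [2, 2, 2], [2, 2, 2])})
        res = contrast_stats(mat, ("wt", "ligand"), ("wt", "vehicle"))
        assert res.at["g", "delta"] == pytest.approx(-1.0)
        assert res.at["g", "fold_change"] == pytest.approx(2.0)
        assert res.at["g", "direction"] == "down"
        # equal variances, equal n: Welch t equals pooled t = delta / (s*sqrt(2/3))
        from scipy import stats as ss

        t, p = ss.ttest_ind([1.0, 1.2, 0.8], [2.0, 2.2, 1.8], equal_var=False)
        assert res.at["g", "p"] == pytest.approx(p)

    def test_replicate_order_irrelevant(self):
        base = {"g1": ([1, 2, 3], [4, 5, 6], [1, 1, 2], [3, 3, 3]),
                "g2": ([2, 2, 2], [2, 2, 3], [9, 8, 7], [1, 2, 1])}
        shuffled = {
            g: tuple(list(reversed(v)) for v in conds) for g, conds in base.items()
        }
        r1 = contrast_stats(_full_matrix(base), ("null", "vehicle"), ("wt", "vehicle"))
        r2 = contrast_stats(_full_matrix(shuffled), ("null", "vehicle"), ("wt", "vehicle"))
        pd.testing.assert_frame_equal(r1, r2)

    def test_zero_variance_nonzero_delta_warns_p_zero(self):
        mat = _full_matrix({"g": ([1, 1, 1], [2, 2, 2], [1, 1, 1], [1, 1, 1])})
        with pytest.warns(UserWarning, match="zero within-group variance"):
            res = contrast_stats(mat, ("wt", "ligand"), ("wt", "vehicle"))
        assert res.at["g", "p"] == 0.0


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.042])[0] == pytest.approx(0.042)

    def test_hand_computed_step_up(self):
        # q_(i) = min_{j>=i} m p_(j) / j -> all 0.04 here
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_ties_map_to_themselves(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_step_up_oracle_and_monotone(self, p_values):
        q = bh_adjust(p_values)
        m = len(p_values)
        order = np.argsort(p_values, kind="stable")
        # direct step-up computation
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, m * p_values[idx] / rank)
            expected[idx] = running
        np.testing.assert_allclose(q, expected, atol=1e-12)
        q_sorted = q[order]
        assert np.all(np.diff(q_sorted) >= -1e-12)  # monotone on sorted input


def _row(fc, direction, q):
    return {"fold_change": fc, "direction": direction, "q": q}


SIG_UP = _row(2.0, "up", 0.01)
SIG_DOWN = _row(2.0, "down", 0.01)
NS = _row(1.05, "up", 0.9)


class TestClassifyGene:
    @pytest.mark.parametrize(
        "lig_wt,geno,lig_null,expected",
        [
            (NS, SIG_UP, NS, "I"),      # knockout-up only: repression
            (NS, SIG_DOWN, NS, "II"),   # knockout-down only: activation
            (SIG_UP, NS, NS, "III"),
            (SIG_DOWN, NS, NS, "IV"),
            (SIG_UP, SIG_UP, NS, "V"),
            (SIG_DOWN, SIG_DOWN, NS, "VI"),
            (SIG_UP, SIG_DOWN, NS, "VII"),
            (SIG_DOWN, SIG_UP, NS, "VIII"),
            (NS, NS, NS, "none"),
            (NS, NS, SIG_UP, "none"),
        ],
    )
    def test_type_mapping(self, lig_wt, geno, lig_null, expected):
        result = classify_gene(lig_wt, geno, lig_null)
        assert result["response_type"] == expected

    def test_ligand_response_in_null_cells_voids_type(self):
        result = classify_gene(SIG_UP, SIG_UP, SIG_UP)
        assert result["response_type"] == "none"
        assert result["ligand_independent"]

    def test_missing_contrast_rejected(self):
        with pytest.raises(ValueError, match="missing contrast"):
            classify_gene(SIG_UP, None, NS)

    def test_threshold_boundaries_inclusive(self):
        thr = ClassifierThresholds(fc_min=1.3, fdr_max=0.25)
        at_boundary = _row(1.3, "up", 0.25)
        assert classify_gene(NS, at_boundary, NS, thr)["response_type"] == "I"
        below = _row(1.29, "up", 0.25)
        assert classify_gene(NS, below, NS, thr)["response_type"] == "none"


class TestClassifyAll:
    def test_partition_and_agreement_with_single_gene_path(self, small_genome):
        _, _, _, manifest = small_genome
        matrix = simulate_expression(manifest, manifest.config)
        table, counts = classify_all(matrix)
        assert sum(counts.values()) == int((table["response_type"] != "none").sum())
        # every gene gets exactly one label, consistent with classify_gene
        for gene in table.index[:40]:
            single = classify_gene(
                {k: table.at[gene, f"ligand_wt_{k}"] for k in ("fold_change", "direction", "q")},
                {k: table.at[gene, f"genotype_{k}"] for k in ("fold_change", "direction", "q")},
                {k: table.at[gene, f"ligand_null_{k}"] for k in ("fold_change", "direction", "q")},
            )
            assert single["response_type"] == table.at[gene, "response_type"]

    def test_null_simulation_controls_false_positives(self):
        cfg = small_sim_config(seed=42, mappable_fraction=1.0)
        cfg = type(cfg)(
            **{
                **cfg.__dict__,
                "expression": type(cfg.expression)(
                    genes_per_type=2, fold_change=1.0
                ),
            }
        )
        _, _, _, manifest = simulate_genome(cfg, with_sequence=False)
        table, counts = classify_all(simulate_expression(manifest, cfg))
        assert sum(counts.values()) <= 0.05 * len(table)

    def test_recovery_at_benchmark_conditions(self, recovery_panel):
        manifest, matrix = recovery_panel
        table, _ = classify_all(matrix)
        planted = {g: t for g, t in manifest.response_types.items() if t != "none"}
        correct = sum(
            1 for g, t in planted.items() if table.at[g, "response_type"] == t
        )
        assert correct / len(planted) >= 0.95

    def test_genotype_relabel_swaps_constitutive_types(self):
        """Swapping wt/null labels maps constitutive-only types I <-> II."""
        rng = np.random.default_rng(7)
        genes = {}
        for i in range(30):
            base = rng.normal(8, 1, size=12).reshape(4, 3)
            shift = 1.0 if i < 15 else -1.0  # I genes then II genes
            base[2] += shift  # null vehicle
            base[3] += shift  # null ligand
            genes[f"g{i:02d}"] = tuple(base.tolist())
        mat = _full_matrix(genes)
        table, _ = classify_all(mat)
        flipped_design = mat.design.copy()
        flipped_design["genotype"] = flipped_design["genotype"].map(
            {"wt": "null", "null": "wt"}
        )
        flipped = ExpressionMatrix(mat.values, flipped_design)
        table2, _ = classify_all(flipped)
        swap = {"I": "II", "II": "I", "none": "none"}
        for g in table.index:
            assert table2.at[g, "response_type"] == swap[table.at[g, "response_type"]]

    def test_switch_ratio_reflects_planted_magnitudes(self, small_genome):
        _, _, _, manifest = small_genome
        matrix = simulate_expression(manifest, manifest.config)
        table, _ = classify_all(matrix)
        ratios = switch_ratio_summary(table)
        # type V planted with equal ligand and knockout shifts -> ratio near 1
        if not np.isnan(ratios["V"]):
            assert 0.5 < ratios["V"] < 2.0


class TestProportions:
    def test_sums_and_percentages(self):
        counts = dict(zip(RESPONSE_TYPES, [185, 297, 71, 28, 12, 9, 1, 9]))
        props = response_type_proportions(counts)
        assert props["total"] == 612
        assert props["major_pct"] == pytest.approx(94.93, abs=0.01)
        assert props["mixed_pct"] == pytest.approx(5.07, abs=0.01)
        assert props["constitutive_total"] == 482
        assert props["ligand_total"] == 99
        assert props["ligand_pct"] == pytest.approx(16.18, abs=0.01)

    def test_missing_type_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            response_type_proportions({"I": 3})
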