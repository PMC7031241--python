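import numpy as np
import pytest
from scipy import stats

from pathctrl import (
    OrthologyMap,
    conservation_test,
    conserved_control_labels,
    control_count_correlation,
)
from pathctrl.conservation import CONSERVED_CONTROL, CONSERVED_NONCONTROL, NO_ORTHOLOG
from pathctrl.pathway_control import ControlProfile

from _oracles import fisher_two_sided_exact


def _map(pairs):
    omap = OrthologyMap()
    for o, h in pairs:
        omap.add("pig", o, h)
    return omap


class TestLabels:
    def test_three_way_labelling(self):
        omap = _map([("p1", "H1"), ("p2", "H2"), ("p3", "H2")])
        labels = conserved_control_labels(
            {"H1", "H2", "H3"}, {"p1", "p3"}, omap, "pig"
        )
        assert labels == {
            "H1": CONSERVED_CONTROL,
            "H2": CONSERVED_CONTROL,  # any-ortholog rule: p3 is a control
            "H3": NO_ORTHOLOG,
        }

    def test_orthologs_without_control_are_noncontrol(self):
        omap = _map([("p1", "H1")])
        labels = conserved_control_labels({"H1"}, set(), omap, "pig")
        assert labels == {"H1": CONSERVED_NONCONTROL}

    def test_unknown_organism_raises(self):
        with pytest.raises(KeyError):
            conserved_control_labels({"H1"}, set(), _map([("p1", "H1")]), "dog")

    def test_labels_partition_universe(self):
        rng = np.random.default_rng(1)
        universe = [f"H{i}" for i in range(50)]
        mapped = rng.choice(universe, size=30, replace=False)
        omap = _map([(f"o_{h}", h) for h in mapped])
        controls = {f"o_{h}" for h in mapped[:10]}
        labels = conserved_control_labels(universe, controls, omap, "pig")
        assert set(labels) == set(universe)
        assert all(v in (CONSERVED_CONTROL, CONSERVED_NONCONTROL, NO_ORTHOLOG)
                   for v in labels.values())


class TestFisher:
    def test_diagonal_table_p_value(self):
        labels = {f"hc{i}": CONSERVED_CONTROL for i in range(10)}
        labels.update({f"hn{i}": CONSERVED_NONCONTROL for i in range(10)})
        res = conservation_test({f"hc{i}" for i in range(10)}, labels)
        assert res.contingency == ((10, 0), (0, 10))
        # 2 / C(20, 10)
        assert res.fisher_p == pytest.approx(2 / 184756, rel=1e-6)

    def test_independent_table_p_is_one(self):
        labels = {}
        controls = set()
        for i in range(10):
            lab = CONSERVED_CONTROL if i % 2 == 0 else CONSERVED_NONCONTROL
            labels[f"c{i}"] = lab
            labels[f"n{i}"] = lab
            controls.add(f"c{i}")
        res = conservation_test(controls, labels)
        assert res.contingency == ((5, 5), (5, 5))
        assert res.fisher_p == 1.0

    def test_degenerate_margin_reports_p_one(self):
        labels = {f"h{i}": CONSERVED_NONCONTROL for i in range(6)}
        res = conservation_test({"h0"}, labels)
        assert res.fisher_p == 1.0

    def test_unmapped_excluded_by_default_included_on_request(self):
        labels = {"H1": CONSERVED_CONTROL, "H2": NO_ORTHOLOG, "H3": CONSERVED_NONCONTROL}
        res = conservation_test({"H1"}, labels)
        assert sum(sum(row) for row in res.contingency) == 2
        res_all = conservation_test({"H1"}, labels, restrict_to_mapped=False)
        assert sum(sum(row) for row in res_all.contingency) == 3

    def test_scipy_agrees_with_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_two_sided_exact(a, b, c, d), rel=1e-8, abs=1e-12)

    def test_permuted_labels_give_uniform_p_values(self):
        rng = np.random.default_rng(4)
        universe = [f"H{i}" for i in range(60)]
        controls = set(universe[:15])
        ps = []
        for _ in range(500):
            conserved = rng.choice(universe, size=20, replace=False)
            labels = {
                h: (CONSERVED_CONTROL if h in set(conserved) else CONSERVED_NONCONTROL)
                for h in universe
            }
            ps.append(conservation_test(controls, labels).fisher_p)
        ps = np.asarray(ps)
        # discrete exact-test p-values are valid (super-uniform): the
        # empirical CDF must not exceed uniform beyond sampling noise
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            rejection_rate = float(np.mean(ps <= alpha))
            assert rejection_rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 500)
        # and the null should still produce small and large p-values
        assert ps.min() < 0.1 and ps.max() > 0.9


class TestCorrelation:
    def _profiles(self, human_counts, org_counts):
        hp = ControlProfile(counts=dict(human_counts), pathway_controls={})
        op = ControlProfile(counts=dict(org_counts), pathway_controls={})
        return hp, op

    def test_identity_orthology_gives_perfect_correlation(self):
        counts = {f"H{i}": i % 7 for i in range(30)}
        omap = _map([(f"o{h}", h) for h in counts])
        hp, op = self._profiles(counts, {f"o{h}": c for h, c in counts.items()})
        rho, p = control_count_correlation(hp, op, omap, "pig")
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        counts = {f"H{i}": i for i in range(10)}
        omap = _map([(f"o{h}", h) for h in counts])
        hp, op = self._profiles(counts, {f"oH{i}": 9 - i for i in range(10)})
        rho, _ = control_count_correlation(hp, op, omap, "pig")
        assert rho == pytest.approx(-1.0)

    def test_max_over_orthologs_is_used(self):
        hp, op = self._profiles({"H1": 5, "H2": 1, "H3": 2},
                                {"a": 0, "b": 5, "c": 1, "d": 2})
        omap = _map([("a", "H1"), ("b", "H1"), ("c", "H2"), ("d", "H3")])
        rho, _ = control_count_correlation(hp, op, omap, "pig")
        assert rho == pytest.approx(1.0)

    def test_too_few_pairs_or_no_variance_is_nan(self):
        hp, op = self._profiles({"H1": 1, "H2": 2}, {"oH1": 1, "oH2": 2})
        omap = _map([("oH1", "H1"), ("oH2", "H2")])
        rho, p = control_count_correlation(hp, op, omap, "pig")
        assert np.isnan(rho)
        hp2, op2 = self._profiles({f"H{i}": 3 for i in range(5)},
                                  {f"oH{i}": i for i in range(5)})
        omap2 = _map([(f"oH{i}", f"H{i}") for i in range(5)])
        rho2, _ = control_count_correlation(hp2, op2, omap2, "pig")
        assert np.isnan(rho2)

    def test_pearson_option(self):
        counts = {f"H{i}": i for i in range(10)}
        omap = _map([(f"o{h}", h) for h in counts])
        hp, op = self._profiles(counts, {f"oH{i}": 2 * i for i in range(10)})
        rho, _ = control_count_correlation(hp, op, omap, "pig", method="pearson")
        assert rho == pytest.approx(1.0)
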