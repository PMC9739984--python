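import numpy as np
import pytest
from scipy import stats as sps

from enf.ca import (
    CAResult,
    ContingencyTable,
    association_verdict,
    build_table,
    correspondence,
    nearest_row_assignment,
)
from enf.errors import ValidationError
from enf.strata import TertileAssignment


def chi2_direct(counts):
    """Independence chi-square by an explicit loop over cells (oracle)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    total = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            e = counts[i].sum() * counts[:, j].sum() / n
            total += (counts[i, j] - e) ** 2 / e
    return total


def make_table(counts, rows=None, cols=None):
    counts = np.asarray(counts, dtype=float)
    rows = rows or [f"row{i}" for i in range(counts.shape[0])]
    cols = cols or [f"col{j}" for j in range(counts.shape[1])]
    return ContingencyTable(rows, cols, counts)


class TestCorrespondence:
    def test_independence_table_zero_inertia(self):
        counts = np.outer([30, 50, 20], [10, 25, 15, 50]) / 100.0
        res = correspondence(make_table(counts))
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.row_coords, 0.0, atol=1e-9)
        np.testing.assert_allclose(res.col_coords, 0.0, atol=1e-9)

    def test_2x2_closed_form_chi2(self):
        # n(ad - bc)^2 / (r1 r2 c1 c2) = 60 * 300^2 / 30^4 = 20/3
        res = correspondence(make_table([[20, 10], [10, 20]]))
        assert res.chi2 == pytest.approx(20 / 3, rel=1e-12)
        assert res.df == 1

    def test_inertia_identity_on_random_tables(self, rng):
        """n x total inertia equals the chi-square computed by direct loop,
        on 120 random tables of varied shape."""
        for _ in range(120):
            shape = (int(rng.integers(2, 5)), int(rng.integers(2, 6)))
            counts = rng.integers(1, 40, size=shape)
            res = correspondence(make_table(counts))
            assert res.n * res.total_inertia == pytest.approx(
                chi2_direct(counts), rel=1e-9)
            assert res.principal_inertias.sum() == pytest.approx(
                res.total_inertia, rel=1e-9)
            assert len(res.principal_inertias) == min(shape) - 1

    def test_matches_scipy_chi2_contingency(self, rng):
        counts = rng.integers(5, 30, size=(3, 4))
        res = correspondence(make_table(counts))
        chi2, p, df, _ = sps.chi2_contingency(counts, correction=False)
        assert res.chi2 == pytest.approx(chi2, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)
        assert res.df == df

    def test_transpose_swaps_coordinates(self, rng):
        counts = rng.integers(1, 30, size=(3, 5))
        a = correspondence(make_table(counts))
        b = correspondence(make_table(counts.T))
        np.testing.assert_allclose(np.sort(a.principal_inertias),
                                   np.sort(b.principal_inertias), rtol=1e-9)
        # coordinates agree up to per-axis sign of the SVD
        for k in range(a.row_coords.shape[1]):
            col = b.col_coords[:, k]
            assert (np.allclose(a.row_coords[:, k], col, atol=1e-9)
                    or np.allclose(a.row_coords[:, k], -col, atol=1e-9))

    def test_weighted_mean_of_coordinates_is_zero(self, rng):
        counts = rng.integers(1, 30, size=(3, 4))
        res = correspondence(make_table(counts))
        r = counts.sum(axis=1) / counts.sum()
        c = counts.sum(axis=0) / counts.sum()
        np.testing.assert_allclose(r @ res.row_coords, 0.0, atol=1e-9)
        np.testing.assert_allclose(c @ res.col_coords, 0.0, atol=1e-9)

    def test_reconstruction_from_decomposition(self, rng):
        """P is rebuilt from margins plus the rescaled decomposition."""
        counts = rng.integers(1, 30, size=(4, 4))
        table = make_table(counts)
        res = correspondence(table)
        P = counts / counts.sum()
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        # standard coordinates = principal / sigma; S = Dr^1/2 Phi Sigma Psi^T Dc^1/2
        sigma = np.sqrt(res.principal_inertias)
        keep = sigma > 1e-12
        phi = res.row_coords[:, keep] / sigma[keep]
        psi = res.col_coords[:, keep] / sigma[keep]
        S = (np.sqrt(r)[:, None] * phi) * sigma[keep] @ \
            (np.sqrt(c)[:, None] * psi).T
        rebuilt = np.outer(r, c) + np.sqrt(np.outer(r, c)) * S
        np.testing.assert_allclose(rebuilt, P, atol=1e-9)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValidationError):
            make_table([[0, 0], [5, 5]])


class TestBuildTable:
    def _tertiles(self, labels):
        return [TertileAssignment(f"r{i}", "CF", lbl)
                for i, lbl in enumerate(labels)]

    def test_balanced_six_respondents(self):
        tertiles = self._tertiles(["low", "low", "medium", "medium",
                                   "high", "high"])
        covariates = {f"r{i}": ("A" if i % 2 == 0 else "B")
                      for i in range(6)}
        table = build_table(tertiles, covariates)
        assert table.row_labels == ["low", "medium", "high"]
        np.testing.assert_array_equal(table.counts, np.ones((3, 2)))

    def test_missing_covariate_dropped(self, caplog):
        tertiles = self._tertiles(["low", "medium", "high", "low", "medium",
                                   "high"])
        covariates = {f"r{i}": "A" for i in range(5)}
        covariates["r5"] = "DA/DK"
        covariates["r0"] = "B"
        import logging
        with caplog.at_level(logging.INFO, logger="enf.ca"):
            table = build_table(tertiles, covariates)
        assert table.counts.sum() == 5
        assert "dropped 1" in caplog.text

    def test_disjoint_ids_rejected(self):
        tertiles = self._tertiles(["low", "medium", "high"])
        with pytest.raises(ValidationError):
            build_table(tertiles, {"zz": "A"})


class TestAssociationVerdict:
    def _result(self, p):
        return CAResult(["low", "medium", "high"], ["A", "B"],
                        np.zeros((3, 2)), np.zeros((2, 2)),
                        np.array([0.1, 0.0]), 0.1, chi2=5.0, df=2,
                        p_value=p, critical_chi2=5.991, n=50)

    @pytest.mark.parametrize("p, expected", [
        (0.21, "not_associated"),   # the null verdict a weak association gets
        (0.001, "associated"),
        (0.05, "not_associated"),   # boundary: strict inequality
    ])
    def test_p_value_rule(self, p, expected):
        verdict, rationale = association_verdict(self._result(p), alpha=0.05)
        assert verdict == expected
        assert "critical" in rationale  # literal rule surfaced, not enforced


def test_nearest_tertile_by_chi_square_distance():
    counts = [[30, 2], [10, 10], [2, 30]]
    res = correspondence(make_table(counts, rows=["low", "medium", "high"],
                                    cols=["A", "B"]))
    nearest = nearest_row_assignment(res)
    assert nearest["A"] == "low" and nearest["B"] == "high"
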