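import numpy as np
import pandas as pd
import pytest

from tissuenet import RegulatorSet, SimConfig, generate_dataset, rank_regulators, rif_scores, state_correlations
from tissuenet.errors import ValidationError
from tissuenet.exprio import log_transform
from tissuenet.normalization import NormalizedExpression
from tissuenet.rif import RIF_CRITERIA


def _adjusted(mat, sheet):
    """Library-centred log2 expression as the co-expression substrate."""
    logm = log_transform(mat)
    return NormalizedExpression(mat.gene_ids, mat.library_ids, logm - logm.mean(axis=0)[None, :])


class TestStateCorrelations:
    def test_self_correlation_is_one(self, small_dataset):
        _, mat, sheet, _ = small_dataset
        norm = _adjusted(mat, sheet)
        g = mat.gene_ids[0]
        r1, r2 = state_correlations(norm, sheet, [g], [g])
        assert r1.loc[g, g] == pytest.approx(1.0)
        assert r2.loc[g, g] == pytest.approx(1.0)

    def test_residualized_profile_near_zero(self, small_dataset, rng):
        _, mat, sheet, _ = small_dataset
        norm = _adjusted(mat, sheet)
        g0, g1 = mat.gene_ids[:2]
        i0, i1 = 0, 1
        vals = norm.values.copy()
        for state in ("PRE", "POST"):
            m = sheet.mask(state=state)
            x, y = vals[i0, m], vals[i1, m]
            x = x - x.mean()
            y = y - y.mean()
            vals[i1, m] = y - (x @ y) / (x @ x) * x  # residualize target on regulator
        norm2 = NormalizedExpression(norm.gene_ids, norm.library_ids, vals)
        r1, r2 = state_correlations(norm2, sheet, [g0], [g1])
        assert abs(r1.loc[g0, g1]) < 0.15
        assert abs(r2.loc[g0, g1]) < 0.15

    def test_planted_rewiring_dw(self):
        cfg = SimConfig(n_genes=300, n_de=40, n_regulators=10, n_rewired_regulators=2,
                        rewire_strength=1.0, n_targets_per_regulator=10, seed=5,
                        variance_components=(1.0, 0.3, 0.05, 0.005, 0.2), baseline_mean=8.0)
        mat, sheet, truth = generate_dataset(cfg)
        norm = _adjusted(mat, sheet)
        for r in truth.rewired_regulators:
            targets = truth.regulator_targets[r]
            r1, r2 = state_correlations(norm, sheet, [r], targets)
            dw = (r1 - r2).to_numpy()
            assert np.abs(dw).mean() >= 0.5

    def test_zero_variance_flagged(self, small_dataset):
        _, mat, sheet, _ = small_dataset
        norm = _adjusted(mat, sheet)
        vals = norm.values.copy()
        vals[3, :] = 0.0
        norm2 = NormalizedExpression(norm.gene_ids, norm.library_ids, vals)
        flat, other = mat.gene_ids[3], mat.gene_ids[5]
        r1, _ = state_correlations(norm2, sheet, [flat], [other])
        assert r1.loc[flat, other] == 0.0
        assert flat in r1.attrs["zero_variance_regulators"]

    def test_too_few_libraries(self, small_dataset):
        _, mat, sheet, _ = small_dataset
        from tissuenet.exprio import SampleSheet

        frame = pd.concat(
            [sheet.frame[sheet.frame["state"] == "PRE"].head(2),
             sheet.frame[sheet.frame["state"] == "POST"]]
        )
        small_sheet = SampleSheet(frame)
        cols = [mat.library_ids.index(l) for l in small_sheet.libraries]
        norm = NormalizedExpression(mat.gene_ids, small_sheet.libraries,
                                    np.log2(mat.values[:, cols]))
        with pytest.raises(ValidationError, match="PRE"):
            state_correlations(norm, small_sheet, [mat.gene_ids[0]], [mat.gene_ids[1]])


class TestRifScores:
    def _series(self, names, vals):
        return pd.Series(vals, index=names, dtype=float)

    def test_hand_case(self):
        reg = RegulatorSet(["r"], ["t1", "t2"])
        r1 = pd.DataFrame([[0.5, 0.2]], index=["r"], columns=["t1", "t2"])
        r2 = pd.DataFrame([[0.0, 0.0]], index=["r"], columns=["t1", "t2"])
        a = self._series(["t1", "t2"], [1.0, 2.0])
        d = self._series(["t1", "t2"], [1.0, -1.0])
        e = self._series(["t1", "t2"], [0.0, 0.0])
        out = rif_scores(reg, r1, r2, a, d, e, e)
        # (1*1*0.25 + 2*(-1)*0.04) / 2
        assert out.loc["r", "rif1_raw"] == pytest.approx(0.085)

    def test_zero_dw_zero_rif1(self):
        reg = RegulatorSet(["r"], ["t1", "t2"])
        same = pd.DataFrame([[0.4, -0.3]], index=["r"], columns=["t1", "t2"])
        a = self._series(["t1", "t2"], [1.0, 2.0])
        d = self._series(["t1", "t2"], [1.0, 1.0])
        e = self._series(["t1", "t2"], [1.0, 1.0])
        out = rif_scores(reg, same, same.copy(), a, d, e, e)
        assert out.loc["r", "rif1_raw"] == 0.0

    def test_balanced_wiring_zero_rif2(self):
        reg = RegulatorSet(["r"], ["t1"])
        r1 = pd.DataFrame([[0.6]], index=["r"], columns=["t1"])
        r2 = pd.DataFrame([[-0.6]], index=["r"], columns=["t1"])
        a = self._series(["t1"], [1.0])
        d = self._series(["t1"], [1.0])
        e1 = self._series(["t1"], [2.0])
        e2 = self._series(["t1"], [2.0])
        out = rif_scores(reg, r1, r2, a, d, e1, e2)
        assert out.loc["r", "rif2_raw"] == pytest.approx(0.0)

    def test_state_swap_negates_both(self, rng):
        regs = [f"r{i}" for i in range(5)]
        tgts = [f"t{i}" for i in range(7)]
        r1 = pd.DataFrame(rng.uniform(-1, 1, (5, 7)), index=regs, columns=tgts)
        r2 = pd.DataFrame(rng.uniform(-1, 1, (5, 7)), index=regs, columns=tgts)
        a = self._series(tgts, rng.uniform(1, 5, 7))
        d = self._series(tgts, rng.normal(0, 1, 7))
        e1 = self._series(tgts, rng.uniform(1, 5, 7))
        e2 = self._series(tgts, rng.uniform(1, 5, 7))
        reg = RegulatorSet(regs, tgts)
        fwd = rif_scores(reg, r1, r2, a, d, e1, e2)
        rev = rif_scores(reg, r2, r1, a, -d, e2, e1)
        np.testing.assert_allclose(rev["rif1_raw"], -fwd["rif1_raw"], atol=1e-12)
        np.testing.assert_allclose(rev["rif2_raw"], -fwd["rif2_raw"], atol=1e-12)

    def test_z_standardization(self, rng):
        regs = [f"r{i}" for i in range(40)]
        tgts = [f"t{i}" for i in range(10)]
        reg = RegulatorSet(regs, tgts)
        r1 = pd.DataFrame(rng.uniform(-1, 1, (40, 10)), index=regs, columns=tgts)
        r2 = pd.DataFrame(rng.uniform(-1, 1, (40, 10)), index=regs, columns=tgts)
        a = self._series(tgts, rng.uniform(1, 5, 10))
        d = self._series(tgts, rng.normal(0, 1, 10))
        out = rif_scores(reg, r1, r2, a, d, a, a)
        for col in ("rif1_z", "rif2_z"):
            assert out[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert out[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_self_pair_excluded(self):
        # a regulator that is its own target contributes nothing for itself
        reg = RegulatorSet(["r", "s"], ["r", "x"])
        r1 = pd.DataFrame([[1.0, 0.5], [0.2, 0.3]], index=["r", "s"], columns=["r", "x"])
        r2 = pd.DataFrame(0.0, index=["r", "s"], columns=["r", "x"])
        a = self._series(["r", "x"], [1.0, 1.0])
        d = self._series(["r", "x"], [1.0, 1.0])
        e = self._series(["r", "x"], [1.0, 1.0])
        out = rif_scores(reg, r1, r2, a, d, e, e)
        assert out.loc["r", "rif1_raw"] == pytest.approx(0.5**2 / 2)


class TestRankRegulators:
    def _criteria(self, rng, n=20):
        idx = pd.Index([f"r{i}" for i in range(n)], name="regulator")
        return pd.DataFrame(
            {c: rng.normal(size=n) for c in RIF_CRITERIA}, index=idx
        )

    def test_uniform_winner(self, rng):
        crit = self._criteria(rng)
        crit.loc["r0"] = 99.0  # strongest |value| on every criterion
        ranked = rank_regulators(crit)
        assert ranked.index[0] == "r0"
        assert ranked.loc["r0", "aggregate_rank"] == 1.0

    def test_row_order_invariance(self, rng):
        crit = self._criteria(rng)
        ranked1 = rank_regulators(crit)
        ranked2 = rank_regulators(crit.sample(frac=1.0, random_state=1))
        assert list(ranked1.index) == list(ranked2.index)

    def test_missing_column_named(self, rng):
        crit = self._criteria(rng).drop(columns=["max_de"])
        with pytest.raises(ValidationError, match="max_de"):
            rank_regulators(crit)
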