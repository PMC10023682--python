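"""AF burden, burden error, severity taxonomy and evaluation statistics."""
import math

import numpy as np
import pandas as pd
import pytest

from arnet2.metrics import (classify_severity, compute_afb,
                            compute_eaf, evaluate_cohort, evaluate_windows,
                            patient_diagnosis, summarize_eaf)


class TestComputeAfb:
    @pytest.mark.parametrize("t,y,afb,af_time", [
        ([1000.0] * 4, [0, 0, 0, 0], 0.0, 0.0),
        ([30000.0, 60000.0, 10000.0], [1, 0, 1], 0.40, 40000.0),
        ([500.0, 700.0], [1, 1], 1.0, 1200.0),
    ])
    def test_worked_values(self, t, y, afb, af_time):
        b = compute_afb(t, y)
        assert b.afb == pytest.approx(afb, abs=1e-15)
        assert b.total_af_time_ms == pytest.approx(af_time)
        assert b.n_windows == len(t)

    def test_empty_is_missing_not_zero(self):
        assert compute_afb([], []) is None

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            compute_afb([1000.0, 0.0], [0, 1])

    def test_invariances(self, rng):
        t = rng.uniform(20000, 70000, 50)
        y = rng.integers(0, 2, 50)
        base = compute_afb(t, y).afb
        perm = rng.permutation(50)
        assert compute_afb(t[perm], y[perm]).afb == pytest.approx(base, rel=1e-12)
        assert compute_afb(t * 3.7, y).afb == pytest.approx(base, rel=1e-12)


class TestComputeEaf:
    @pytest.mark.parametrize("t,y,yh,expected", [
        ([1000.0, 2000.0], [1, 0], [1, 0], 0.0),
        ([5000.0, 5000.0], [0, 0], [1, 1], 100.0),
        ([10000.0, 30000.0], [1, 0], [0, 1], 50.0),
    ])
    def test_worked_values(self, t, y, yh, expected):
        assert compute_eaf(t, y, yh) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_eaf([1.0], [0], [0, 1])

    def test_identity_with_afb_difference(self, rng):
        """E_AF == 100*(AFB(yhat) - AFB(y)) to 1e-12 on random inputs."""
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            t = rng.uniform(1000, 90000, n)
            y = rng.integers(0, 2, n)
            yh = rng.integers(0, 2, n)
            eaf = compute_eaf(t, y, yh)
            assert -100.0 - 1e-9 <= eaf <= 100.0 + 1e-9
            delta = 100.0 * (compute_afb(t, yh).afb - compute_afb(t, y).afb)
            assert eaf == pytest.approx(delta, abs=1e-12)


class TestSeverityAndDiagnosis:
    @pytest.mark.parametrize("time_ms,afb,level", [
        (20_000.0, 0.01, "NON_AFL"),
        (120_000.0, 0.02, "AF_MILD"),
        (72_000_000.0 * 0.85, 0.85, "AF_SEV"),
        # boundary conventions: strict reading of the printed inequalities
        (30_000.0, 0.001, "AF_MILD"),     # exactly 30 s is no longer "<30 s"
        (400_000.0, 0.04, "AF_MOD"),      # exactly 4%
        (4_000_000.0, 0.80, "AF_MOD"),    # exactly 80% stays in the 4-80% range
        (4_000_001.0, 0.801, "AF_SEV"),
    ])
    def test_taxonomy(self, time_ms, afb, level):
        assert classify_severity(time_ms, afb) == level

    @pytest.mark.parametrize("afb,expected", [
        (0.05, 1), (0.039, 0), (0.04, 1), (0.0, 0), (1.0, 1),
    ])
    def test_patient_diagnosis(self, afb, expected):
        assert patient_diagnosis(afb) == expected

    def test_missing_burden_missing_diagnosis(self):
        assert patient_diagnosis(None) is None

    def test_severity_levels_partition_burden_axis(self):
        """Planted burdens map back to their intended strata."""
        day_ms = 24 * 3600 * 1000.0
        for b, level in [(0.0, "NON_AFL"), (0.02, "AF_MILD"),
                         (0.5, "AF_MOD"), (0.9, "AF_SEV")]:
            time_ms = b * day_ms
            assert classify_severity(time_ms, b) == level


def _auroc_concordance(y, p):
    """O(n^2) pairwise-concordance oracle for AUROC."""
    pos = p[y == 1]
    neg = p[y == 0]
    wins = sum((pp > nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
    return wins / (len(pos) * len(neg))


class TestEvaluateWindows:
    def test_two_by_two_table(self):
        rep = evaluate_windows([1, 0, 1, 0], [1, 1, 0, 0])
        assert (rep.se, rep.sp, rep.ppv, rep.npv, rep.f1) == (0.5, 0.5, 0.5, 0.5, 0.5)

    def test_perfect_ranking(self):
        rep = evaluate_windows([1, 0, 1, 0], [1, 0, 1, 0], [0.9, 0.1, 0.8, 0.2])
        assert rep.auroc == 1.0 and rep.aucpr == 1.0

    def test_f1_is_harmonic_mean_of_se_ppv(self, rng):
        y = rng.integers(0, 2, 200)
        yh = rng.integers(0, 2, 200)
        rep = evaluate_windows(y, yh)
        if not math.isnan(rep.ppv) and rep.se + rep.ppv > 0:
            assert rep.f1 == pytest.approx(2 * rep.se * rep.ppv / (rep.se + rep.ppv))

    def test_auroc_matches_concordance_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            p = np.round(rng.random(n), 2)  # force ties
            rep = evaluate_windows(y, (p > 0.5).astype(int), p)
            assert rep.auroc == pytest.approx(_auroc_concordance(y, p), abs=1e-12)

    def test_single_class_rank_metrics_missing(self):
        rep = evaluate_windows([1, 1], [1, 0], [0.6, 0.4])
        assert math.isnan(rep.auroc) and math.isnan(rep.aucpr)
        assert rep.se == 0.5

    def test_undefined_ppv_reported_missing_f1_zero(self):
        rep = evaluate_windows([1, 0], [0, 0])
        assert math.isnan(rep.ppv) and rep.f1 == 0.0


class TestQuartiles:
    def test_linear_interpolation(self):
        med, q1, q3 = summarize_eaf([-1.0, 2.0, 3.0, 4.0])
        # |values| = [1,2,3,4]; linear-interpolated quartiles
        assert (q1, med, q3) == (1.75, 2.5, 3.25)


class TestEvaluateCohort:
    def _frames(self, n_rec=20, seed=0):
        rng = np.random.Generator(np.random.PCG64(seed))
        wrows, rrows = [], []
        rates = [0.0, 0.02, 0.3, 0.8]
        for i in range(n_rec):
            rid = f"r{i:02d}"
            n = 30
            t = rng.uniform(30000, 60000, n)
            y = (rng.random(n) < rates[i % 4]).astype(int)
            yh = y.copy()
            flip = rng.random(n) < 0.1
            yh[flip] = 1 - yh[flip]
            p = np.where(yh == 1, rng.uniform(0.6, 1.0, n), rng.uniform(0.0, 0.4, n))
            for k in range(n):
                wrows.append({"record_id": rid, "t_ms": t[k], "y": int(y[k]),
                              "y_hat": int(yh[k]), "p": p[k]})
            true_afb = compute_afb(t, y).afb
            est_afb = compute_afb(t, yh).afb
            rrows.append({"record_id": rid, "true_afb": true_afb,
                          "true_af_time_ms": compute_afb(t, y).total_af_time_ms,
                          "est_afb": est_afb, "site": "A" if i % 2 else "B"})
        return pd.DataFrame(wrows), pd.DataFrame(rrows)

    def test_perfect_predictions_are_all_ones(self):
        wdf, rdf = self._frames()
        wdf["y_hat"] = wdf["y"]
        wdf["p"] = wdf["y"].astype(float)
        rdf["est_afb"] = rdf["true_afb"]
        out = evaluate_cohort(wdf, rdf)
        rep = out["window"][0]
        assert rep.se == rep.sp == rep.f1 == rep.auroc == 1.0
        assert rep.eaf_abs_median == 0.0
        assert out["patient"].se == out["patient"].sp == 1.0
        assert len(out["fn_audit"]) == 0

    def test_identical_strata_identical_reports(self):
        wdf, rdf = self._frames()
        rdf["dup"] = "same"
        out = evaluate_cohort(wdf, rdf, strata=["dup"])
        pooled, stratum = out["window"][0], out["window"][1]
        for fieldname in ("se", "sp", "f1", "auroc", "eaf_abs_median"):
            a, b = getattr(pooled, fieldname), getattr(stratum, fieldname)
            assert a == pytest.approx(b, abs=1e-12)

    def test_patient_level_matches_hand_tally(self):
        wdf, rdf = self._frames(n_rec=20, seed=3)
        out = evaluate_cohort(wdf, rdf)
        yt = (rdf["true_afb"] >= 0.04).astype(int).to_numpy()
        yp = (rdf["est_afb"] >= 0.04).astype(int).to_numpy()
        tp = int(((yt == 1) & (yp == 1)).sum())
        fn = int(((yt == 1) & (yp == 0)).sum())
        tn = int(((yt == 0) & (yp == 0)).sum())
        fp = int(((yt == 0) & (yp == 1)).sum())
        pat = out["patient"]
        assert (pat.tp, pat.fn, pat.tn, pat.fp) == (tp, fn, tn, fp)
        if tp + fn:
            assert pat.se == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert pat.sp == pytest.approx(tn / (tn + fp))
        assert len(out["fn_audit"]) == fn
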