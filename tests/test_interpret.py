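"""Blanking mechanics, attribution estimator, aggregation, cooperativity."""

import numpy as np
import pytest
from scipy import stats as sps

from tracenet import nn
from tracenet.interpret import (
    InterpretError,
    aggregate_extreme_decile,
    attribution_significance_map,
    blank_window,
    blanking_scan,
    compute_attributions,
    cooperativity_map,
    median_distance_of_extreme_decile,
    normalized_predictability,
)
from tracenet.models import TrainedClassifier, ClassifierConfig

B = 52


# ---------------------------------------------------------------------------
# blanking mechanics
# ---------------------------------------------------------------------------

def test_blank_window_full_and_single(rng):
    m = rng.normal(size=(B, B))
    assert (blank_window(m, 0, B) == 0).all()
    k = 7
    out = blank_window(m, k, 1)
    changed = out != m
    assert changed.sum() == 2 * B - 1
    assert (out[k, :] == 0).all() and (out[:, k] == 0).all()


def test_blank_window_preserves_outside_bitwise(rng):
    m = rng.normal(size=(3, B, B))
    out = blank_window(m, 10, 5)
    mask = np.zeros((B, B), dtype=bool)
    mask[10:15, :] = True
    mask[:, 10:15] = True
    np.testing.assert_array_equal(out[:, ~mask], m[:, ~mask])


def test_blank_window_rejects_raw_and_bad_ranges(rng):
    raw = np.abs(rng.normal(size=(B, B)))
    with pytest.raises(InterpretError, match="raw"):
        blank_window(raw, 0, 5)
    blank_window(raw, 0, 5, assume_standardized=True)  # override works
    z = rng.normal(size=(B, B))
    with pytest.raises(InterpretError):
        blank_window(z, 50, 5)
    with pytest.raises(InterpretError):
        blank_window(z, 0, B + 1)


def test_normalized_predictability_anchors_and_linearity():
    assert normalized_predictability(0.9, 0.9) == pytest.approx(100.0)
    assert normalized_predictability(0.5, 0.9) == pytest.approx(0.0)
    assert normalized_predictability(0.7, 0.9) == pytest.approx(50.0)
    # linearity / monotonicity
    xs = np.linspace(0.5, 0.9, 9)
    ys = [normalized_predictability(x, 0.9) for x in xs]
    np.testing.assert_allclose(np.diff(ys), np.diff(ys)[0])
    with pytest.raises(InterpretError):
        normalized_predictability(0.6, 0.5)


class _ScoreModel(TrainedClassifier):
    """Deterministic stand-in scoring by one matrix entry."""

    def __init__(self, i, j):
        super().__init__("cnn", ClassifierConfig())
        self.i, self.j = i, j

    def predict_proba(self, matrices):
        m = np.asarray(matrices)
        return 1.0 / (1.0 + np.exp(m[:, self.i, self.j]))


def test_blanking_scan_localizes_score_entry(rng):
    # model reads entry (19, 39); labels follow it; blanking that row kills AUC
    m = rng.normal(size=(400, B, B))
    m = (m + m.transpose(0, 2, 1)) / 2
    labels = (m[:, 19, 39] < 0).astype(int)
    model = _ScoreModel(19, 39)
    prof = blanking_scan(model, m, labels, window_size=5, n_trials=3, seed=0)
    assert prof.predictability.shape == (B - 5 + 1, 3)
    mins = prof.centers[np.argmin(prof.mean_profile())]
    # any window touching barcode 20 or 40 kills this model equally
    assert mins in set(range(18, 23)) | set(range(38, 43))
    assert prof.score_at(20).mean() < 20
    # windows far from both elements change nothing for this model
    assert prof.score_at(10).mean() == pytest.approx(100.0)
    with pytest.raises(InterpretError):
        blanking_scan(model, m, labels, window_size=B + 1)


# ---------------------------------------------------------------------------
# expected gradients
# ---------------------------------------------------------------------------

def _linear_model(w, rng):
    """Single dense layer == linear logit; expected gradients are exact."""
    layer = nn.Dense(B * B, 1, rng, dtype=np.float64)
    layer.w.value[...] = w.reshape(-1, 1)
    layer.b.value[...] = 0.0
    model = TrainedClassifier("dnn", ClassifierConfig(kind="dnn"))
    model.net = nn.Sequential([nn.Flatten(), layer])
    return model


def test_attributions_linear_closed_form(rng):
    w = rng.normal(size=(B, B))
    model = _linear_model(w, rng)
    x = rng.normal(size=(3, B, B))
    bg = rng.normal(size=(20, B, B))
    attr = compute_attributions(model, x, bg, n_samples=1500, seed=0, symmetrize=False)
    # for f(x) = w.x the estimator converges to w * (x - E[bg]); Monte-Carlo
    # error per entry scales with |w_ij| * std(bg) / sqrt(n_samples)
    expected = w[None] * (x - bg.mean(axis=0))
    se = np.abs(w)[None] / np.sqrt(1500) * 4.0 + 0.02
    assert (np.abs(attr - expected) < 5 * se).all()
    # global agreement
    assert np.corrcoef(attr.ravel(), expected.ravel())[0, 1] > 0.999


def test_attributions_zero_at_background(rng):
    w = rng.normal(size=(B, B))
    model = _linear_model(w, rng)
    ref = rng.normal(size=(1, B, B))
    attr = compute_attributions(model, ref.copy(), ref, n_samples=8, seed=0)
    np.testing.assert_allclose(attr, 0.0, atol=1e-12)


def test_attributions_symmetrized_and_rf_rejected(rng):
    w = rng.normal(size=(B, B))
    model = _linear_model(w, rng)
    x = rng.normal(size=(2, B, B))
    attr = compute_attributions(model, x, x, n_samples=4, seed=0)
    np.testing.assert_allclose(attr, attr.transpose(0, 2, 1))
    rf = TrainedClassifier("rf", ClassifierConfig(kind="rf"))
    with pytest.raises(InterpretError):
        compute_attributions(rf, x, x)


# ---------------------------------------------------------------------------
# population-level aggregation
# ---------------------------------------------------------------------------

def test_aggregate_decile_hand_cases():
    n_on, n_off = 20, 15
    attr = np.zeros((n_on + n_off, B, B))
    labels = np.array([1] * n_on + [0] * n_off)
    attr[:n_on, 3, 5] = np.arange(1, n_on + 1)  # 1..20 -> top decile mean 19.5
    attr[:n_on, 7, 9] = 4.2  # constant -> aggregate = 4.2
    attr[n_on:, 2, 8] = -np.arange(1, n_off + 1)
    agg = aggregate_extreme_decile(attr, labels)
    assert agg.on_top_decile_mean[3, 5] == pytest.approx(19.5)
    assert agg.on_top_decile_mean[7, 9] == pytest.approx(4.2)
    # bottom decile of -1..-15 over OFF cells: round(1.5)=2 most negative
    assert agg.off_bottom_decile_mean[2, 8] == pytest.approx((-15 - 14) / 2)
    with pytest.raises(InterpretError):
        aggregate_extreme_decile(attr[:15], labels[:15])  # only 5 OFF cells


def test_aggregate_on_map_dominates_plain_mean(rng):
    attr = rng.normal(size=(40, B, B))
    labels = np.array([1] * 25 + [0] * 15)
    agg = aggregate_extreme_decile(attr, labels)
    plain = attr[labels == 1].mean(axis=0)
    assert (agg.on_top_decile_mean >= plain - 1e-12).all()


def test_median_distance_of_decile_matches_sort_oracle(rng):
    n = 30
    attr = rng.normal(size=(n, B, B))
    dist = np.abs(rng.normal(size=(n, B, B))) * 100
    labels = np.array([1] * 20 + [0] * 10)
    maps = median_distance_of_extreme_decile(attr, dist, labels)
    k = max(1, round(20 * 0.1))
    a_on, d_on = attr[:20], dist[:20]
    for (i, j) in [(0, 1), (10, 40), (51, 3)]:
        order = np.argsort(a_on[:, i, j])
        expected = np.median(d_on[order[-k:], i, j])
        assert maps["on_median_distance"][i, j] == pytest.approx(expected)
    single = median_distance_of_extreme_decile(
        attr[:11], dist[:11], np.array([1] * 10 + [0]), decile=0.1
    )
    # decile of one cell -> that cell's distance
    i, j = 5, 6
    top = np.argmax(attr[:10, i, j])
    assert single["on_median_distance"][i, j] == pytest.approx(dist[top, i, j])


# ---------------------------------------------------------------------------
# significance map
# ---------------------------------------------------------------------------

def test_significance_map_zero_and_signal(rng):
    n = 30
    attr = np.zeros((n, B, B))
    attr[:, 4, 10] = rng.normal(loc=1.0, scale=0.2, size=n)  # strong signal
    labels = np.ones(n, dtype=int)
    labels[:10] = 0
    maps = attribution_significance_map(attr)
    assert maps["pvalue"][0, 0] == 1.0  # all-zero entry convention
    assert maps["pvalue"][4, 10] < 1e-3
    assert maps["pvalue"][10, 4] == maps["pvalue"][4, 10]  # symmetric


def test_signed_rank_matches_hand_computed_eight_values():
    from tracenet.interpret import signed_rank_pvalue

    # frozen 8-value toy: |v| ranks are [5,3,8,2,4,6,1,7], so the negative
    # ranks sum to W- = 3 + 4 = 7; normal approximation:
    # z = (W- - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24) = (7 - 18)/sqrt(51)
    v = np.array([1.2, -0.8, 2.5, 0.6, -1.0, 1.8, 0.4, 2.1])
    ranks = sps.rankdata(np.abs(v))
    w_minus = ranks[v < 0].sum()
    assert w_minus == 7.0
    z = (7.0 - 8 * 9 / 4) / np.sqrt(8 * 9 * 17 / 24)
    hand_p = 2 * sps.norm.cdf(z)
    # scipy applies a continuity correction of 0.5 in the numerator
    z_cc = (7.0 + 0.5 - 18.0) / np.sqrt(51.0)
    hand_p_cc = 2 * sps.norm.cdf(z_cc)
    p = signed_rank_pvalue(v)
    assert min(abs(p - hand_p), abs(p - hand_p_cc)) < 1e-9
    assert signed_rank_pvalue(np.zeros(8)) == 1.0


def test_significance_bh_adjustment_monotone(rng):
    attr = rng.normal(size=(25, B, B)) * 0.1
    attr[:, 0, 1] += 2.0
    raw = attribution_significance_map(attr)["pvalue"]
    adj = attribution_significance_map(attr, bh_adjust=True)["pvalue"]
    assert (adj + 1e-15 >= raw).all()


# ---------------------------------------------------------------------------
# cooperativity
# ---------------------------------------------------------------------------

def test_cooperativity_perfectly_coupled_entries(rng):
    from tracenet.interpret import pairwise_cooccurrence

    n = 200
    attr = rng.normal(size=(n, B, B)) * 0.01
    labels = np.ones(n, dtype=int)
    hot = rng.random(n) < 0.08
    # entries (1,2) and (3,4) extreme in exactly the same cells, with
    # distinct magnitudes so the percentile cutoff falls inside them
    vals = 10.0 + rng.random(hot.sum())
    attr[hot, 1, 2] = vals
    attr[hot, 3, 4] = vals  # identical magnitudes -> identical extreme sets
    pc = pairwise_cooccurrence(attr, labels, (1, 2), side="on", percentile=96.0)
    assert pc[3, 4] == 1.0  # perfectly coupled partner
    assert np.nanmedian(pc) < 0.3  # unrelated entries co-occur at chance


def test_avg_cooccurrence_consistent_with_pairwise(rng):
    from tracenet.interpret import pairwise_cooccurrence

    n = 150
    attr = rng.normal(size=(n, 8, 8))
    labels = np.ones(n, dtype=int)
    cmap = cooperativity_map(attr, labels, side="on", percentile=90.0,
                             n_permutations=0)
    for entry in [(0, 1), (3, 6), (7, 2)]:
        pc = pairwise_cooccurrence(attr, labels, entry, side="on", percentile=90.0)
        mask = np.ones((8, 8), dtype=bool)
        mask[entry] = False
        expected = pc[mask].mean()
        assert cmap.avg_cooccurrence[entry] == pytest.approx(expected)


def test_cooperativity_independent_rate(rng):
    n, r = 400, 0.10
    attr = rng.normal(size=(n, 10, 10))
    labels = np.ones(n, dtype=int)
    cmap = cooperativity_map(attr, labels, side="on", percentile=100 * (1 - r),
                             n_permutations=0)
    vals = cmap.avg_cooccurrence[~np.isnan(cmap.avg_cooccurrence)]
    # independent gaussian entries: expected co-occurrence ~= r
    assert abs(np.mean(vals) - r) < 0.03


def test_save_heatmap_writes_png(rng, tmp_path):
    from tracenet.interpret import save_heatmap

    m = rng.normal(size=(B, B))
    path = tmp_path / "map.png"
    save_heatmap(m, path, title="demo")
    assert path.exists() and path.stat().st_size > 1000


def test_cooperativity_off_side_and_distances(rng):
    n = 100
    attr = rng.normal(size=(n, B, B))
    dist = np.abs(rng.normal(size=(n, B, B))) * 100
    labels = np.zeros(n, dtype=int)
    cmap = cooperativity_map(attr, labels, side="off", percentile=90.0,
                             raw_matrices=dist, n_permutations=20, seed=0)
    assert cmap.side == "off"
    assert np.nanmax(cmap.avg_cooccurrence) <= 1.0
    ok = ~np.isnan(cmap.pvalues)
    assert (cmap.pvalues[ok] > 0).all() and (cmap.pvalues[ok] <= 1).all()
    # median-distance map defined wherever co-occurrence is
    assert not np.isnan(cmap.median_distance[~np.isnan(cmap.avg_cooccurrence)]).any()
    with pytest.raises(InterpretError):
        cooperativity_map(attr, labels, side="sideways")
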