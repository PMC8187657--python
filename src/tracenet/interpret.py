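"""Unpacking what a trained classifier learned.

Three complementary views:

* **Window blanking** — occlusion analysis in matrix space: every entry whose
  row or column falls in a sliding window of barcodes is replaced by the
  training-set average (0 in standardized space), and the AUC drop is
  converted to a *normalized predictability* score where 100 is the
  unblanked AUC and 0 is chance (AUC 0.5).
* **Expected-gradients attribution** — per-example signed maps in the SHAP
  family: the average over background references of
  ``(x - ref) * grad(logit)`` along the straight path from reference to
  input. Positive values push the prediction toward ON. Population-level
  summaries average the top decile of each entry's values over ON cells
  (bottom decile over OFF cells), with companion median-distance and
  signed-rank significance maps.
* **Cooperativity** — for each matrix entry, how often *other* entries are
  simultaneously attribution-extreme in the same cells; hub-like regulatory
  logic (two enhancers needed at once) shows up as elevated co-occurrence.

Barcode/window centers are reported as 1-based barcode numbers, matching
the "monomer 20 / monomer 40" convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from tracenet.models import ModelError, TrainedClassifier, compute_auc


class InterpretError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Blanking
# ---------------------------------------------------------------------------

def blank_window(
    matrices: np.ndarray,
    window_start: int,
    window_size: int,
    fill: float = 0.0,
    assume_standardized: bool = False,
) -> np.ndarray:
    """Replace all entries in the window's rows AND columns with ``fill``.

    ``window_start`` is 0-based; entries outside the window are untouched
    (bitwise). Expects standardized matrices — in z-score space the dataset
    average of every entry is 0, so the default fill erases the window's
    information without shifting the input distribution. A nonnegative input
    is rejected as likely raw unless ``assume_standardized`` is set.
    """
    m = np.array(matrices, dtype=float, copy=True)
    single = m.ndim == 2
    if single:
        m = m[None]
    B = m.shape[-1]
    if not assume_standardized and m.min() >= 0:
        raise InterpretError(
            "input looks like raw distances (all nonnegative); blanking operates "
            "on standardized matrices"
        )
    if window_size < 1 or window_size > B:
        raise InterpretError(f"window_size must be in 1..{B}")
    if window_start < 0 or window_start + window_size > B:
        raise InterpretError("window out of range")
    sl = slice(window_start, window_start + window_size)
    m[:, sl, :] = fill
    m[:, :, sl] = fill
    return m[0] if single else m


def normalized_predictability(auc_blanked: float, auc_base: float) -> float:
    """Linear rescaling: base AUC -> 100, chance (0.5) -> 0."""
    if auc_base <= 0.5:
        raise InterpretError(
            f"base AUC {auc_base:.3f} <= 0.5: predictability scale undefined"
        )
    return 100.0 * (auc_blanked - 0.5) / (auc_base - 0.5)


@dataclass
class BlankingProfile:
    """Normalized predictability per window center per trial.

    ``centers`` are 1-based barcode numbers (window center = start + size//2);
    ``predictability`` has shape (n_centers, n_trials).
    """

    window_size: int
    centers: np.ndarray
    predictability: np.ndarray
    base_auc: float
    base_auc_trials: np.ndarray
    n_trials: int

    def mean_profile(self) -> np.ndarray:
        return self.predictability.mean(axis=1)

    def score_at(self, center: int) -> np.ndarray:
        """All trial scores for the window centered on a 1-based barcode."""
        idx = np.nonzero(self.centers == center)[0]
        if len(idx) == 0:
            raise InterpretError(f"no window centered on barcode {center}")
        return self.predictability[idx[0]]

    def to_frame(self):
        import pandas as pd

        rows = [
            (int(c), t, float(self.predictability[i, t]))
            for i, c in enumerate(self.centers)
            for t in range(self.n_trials)
        ]
        return pd.DataFrame(rows, columns=["center", "trial", "predictability"])


def blanking_scan(
    model: TrainedClassifier,
    matrices: np.ndarray,
    labels: np.ndarray,
    window_size: int,
    n_trials: int = 10,
    seed: int = 0,
    trial_fraction: float = 0.8,
    centers: list[int] | None = None,
) -> BlankingProfile:
    """Slide a blanking window across all barcodes and score each position.

    ``matrices`` are the standardized held-out matrices, ``labels`` their
    ON/OFF states. Dispersion across ``n_trials`` comes from stratified
    subsampling of the held-out set under the single trained model (pass the
    scores through :func:`normalized_predictability` against each trial's own
    unblanked AUC). ``centers`` restricts the scan to specific 1-based window
    centers (default: every admissible position).
    """
    m = np.asarray(matrices, dtype=float)
    y = np.asarray(labels)
    B = m.shape[-1]
    if window_size > B:
        raise InterpretError("window larger than the number of barcodes")
    rng = np.random.default_rng(seed)

    # stratified trial subsets
    on_idx, off_idx = np.nonzero(y == 1)[0], np.nonzero(y == 0)[0]
    trials = []
    if n_trials <= 1 or trial_fraction >= 1.0:
        trials = [np.arange(len(y))] * max(n_trials, 1)
    else:
        for _ in range(n_trials):
            t_on = rng.choice(on_idx, int(round(trial_fraction * len(on_idx))), replace=False)
            t_off = rng.choice(off_idx, int(round(trial_fraction * len(off_idx))), replace=False)
            trials.append(np.concatenate([t_on, t_off]))

    base_scores = model.predict_proba(m)
    base_aucs = np.array([compute_auc(y[t], base_scores[t]) for t in trials])

    starts = np.arange(0, B - window_size + 1)
    if centers is not None:
        wanted = np.asarray(centers)
        starts = wanted - window_size // 2 - 1
        if starts.min() < 0 or starts.max() + window_size > B:
            raise InterpretError(f"centers {centers} out of range for window")
    centers = starts + window_size // 2 + 1  # 1-based
    pred = np.empty((len(starts), len(trials)))
    for i, s in enumerate(starts):
        blanked = blank_window(m, int(s), window_size)
        scores = model.predict_proba(blanked)
        for t_i, t in enumerate(trials):
            auc_b = compute_auc(y[t], scores[t])
            pred[i, t_i] = normalized_predictability(auc_b, base_aucs[t_i])
    return BlankingProfile(
        window_size=window_size,
        centers=centers,
        predictability=pred,
        base_auc=float(base_aucs.mean()),
        base_auc_trials=base_aucs,
        n_trials=len(trials),
    )


# ---------------------------------------------------------------------------
# Expected-gradients attribution
# ---------------------------------------------------------------------------

def compute_attributions(
    model: TrainedClassifier,
    examples: np.ndarray,
    background: np.ndarray,
    n_samples: int = 32,
    seed: int = 0,
    symmetrize: bool = True,
    batch_size: int = 256,
) -> np.ndarray:
    """Per-example signed attribution maps via expected gradients.

    For each example x the attribution is the Monte-Carlo estimate of
    ``E_{r ~ background, a ~ U(0,1)}[(x - r) * dlogit/dx |_{r + a (x - r)}]``,
    i.e. the GradientExplainer estimator of SHAP values with the training
    split as the reference distribution. The logit (pre-sigmoid) output is
    attributed, and maps are symmetrized since the input matrices are
    symmetric. Only differentiable models (cnn/dnn) are supported.
    """
    if model.kind not in ("cnn", "dnn"):
        raise InterpretError(f"attributions unsupported for model kind {model.kind!r}")
    x = np.asarray(examples, dtype=np.float32)
    single = x.ndim == 2
    if single:
        x = x[None]
    bg = np.asarray(background, dtype=np.float32)
    rng = np.random.default_rng(seed)
    N, B = len(x), x.shape[-1]
    attr = np.zeros((N, B, B), dtype=np.float64)
    net = model.net
    for start in range(0, N, batch_size):
        xb = x[start : start + batch_size]
        nb = len(xb)
        acc = np.zeros((nb, B, B), dtype=np.float64)
        for _ in range(n_samples):
            refs = bg[rng.integers(0, len(bg), nb)]
            alphas = rng.random(nb).astype(np.float32)[:, None, None]
            point = refs + alphas * (xb - refs)
            if model.kind == "cnn":
                grad = net.input_gradient(point[:, None]).reshape(nb, B, B)
            else:
                grad = net.input_gradient(point.reshape(nb, -1)).reshape(nb, B, B)
            acc += (xb - refs) * grad
        attr[start : start + nb] = acc / n_samples
    if symmetrize:
        attr = 0.5 * (attr + attr.transpose(0, 2, 1))
    return attr[0] if single else attr


# ---------------------------------------------------------------------------
# Population-level aggregation
# ---------------------------------------------------------------------------

def _decile_count(n: int, decile: float) -> int:
    return max(1, int(round(n * decile)))


@dataclass
class AggregateMaps:
    on_top_decile_mean: np.ndarray
    off_bottom_decile_mean: np.ndarray
    on_median_distance: np.ndarray | None = None
    off_median_distance: np.ndarray | None = None
    on_pvalue: np.ndarray | None = None
    off_pvalue: np.ndarray | None = None


def aggregate_extreme_decile(
    attributions: np.ndarray,
    labels: np.ndarray,
    decile: float = 0.1,
) -> AggregateMaps:
    """Entrywise mean of each entry's strongest attributions per class.

    ON map: per entry, the mean over the top decile of that entry's values
    across ON cells. OFF map: the mean over the bottom (most negative)
    decile across OFF cells. Emphasizes rare-but-strong predictive features
    that plain averaging would cancel out.
    """
    a = np.asarray(attributions)
    y = np.asarray(labels)
    a_on, a_off = a[y == 1], a[y == 0]
    if len(a_on) < 10 or len(a_off) < 10:
        raise InterpretError("need >=10 cells per class for decile aggregation")
    k_on = _decile_count(len(a_on), decile)
    k_off = _decile_count(len(a_off), decile)
    srt_on = np.sort(a_on, axis=0)
    srt_off = np.sort(a_off, axis=0)
    return AggregateMaps(
        on_top_decile_mean=srt_on[-k_on:].mean(axis=0),
        off_bottom_decile_mean=srt_off[:k_off].mean(axis=0),
    )


def median_distance_of_extreme_decile(
    attributions: np.ndarray,
    raw_matrices: np.ndarray,
    labels: np.ndarray,
    decile: float = 0.1,
) -> dict:
    """Median RAW distance over the cells selected by the decile rule.

    Per entry: the same ON-cell top-decile (OFF-cell bottom-decile) subset
    used for aggregation, but reporting the median of those cells' physical
    distances (nm) at that entry — revealing whether a predictive entry acts
    through proximity or separation.
    """
    a = np.asarray(attributions)
    d = np.asarray(raw_matrices, dtype=float)
    y = np.asarray(labels)
    if a.shape != d.shape:
        raise InterpretError("attribution/distance pairing mismatch")
    out = {}
    for name, cls, top in (("on", 1, True), ("off", 0, False)):
        a_c, d_c = a[y == cls], d[y == cls]
        if len(a_c) < 1:
            raise InterpretError(f"no cells in class {name}")
        k = _decile_count(len(a_c), decile)
        order = np.argsort(a_c, axis=0)
        sel = order[-k:] if top else order[:k]
        picked = np.take_along_axis(d_c, sel, axis=0)
        out[f"{name}_median_distance"] = np.median(picked, axis=0)
    return out


def signed_rank_pvalue(values: np.ndarray) -> float:
    """One-sample Wilcoxon signed-rank p-value against zero (normal approx).

    All-zero input returns 1.0 by convention.
    """
    v = np.asarray(values, dtype=float)
    if np.allclose(v, 0.0):
        return 1.0
    res = stats.wilcoxon(v, zero_method="wilcox", method="approx")
    return float(res.pvalue)


def attribution_significance_map(
    attributions: np.ndarray,
    labels: np.ndarray | None = None,
    bh_adjust: bool = False,
) -> dict:
    """Per-entry one-sample Wilcoxon signed-rank test of attributions vs 0.

    Run within each class when labels are given (keys ``on_pvalue`` /
    ``off_pvalue``), else over all cells (key ``pvalue``). All-zero entries
    get p = 1 by convention. ``bh_adjust`` applies Benjamini–Hochberg across
    the unique (upper-triangle incl. diagonal) entries.
    """
    a = np.asarray(attributions)
    groups = (
        {"pvalue": a}
        if labels is None
        else {
            "on_pvalue": a[np.asarray(labels) == 1],
            "off_pvalue": a[np.asarray(labels) == 0],
        }
    )
    out = {}
    for key, arr in groups.items():
        if len(arr) < 10:
            raise InterpretError("need >=10 cells per class for significance maps")
        B = arr.shape[-1]
        pm = np.ones((B, B))
        iu = np.triu_indices(B)
        pvals = np.asarray(
            [signed_rank_pvalue(arr[:, i, j]) for i, j in zip(*iu)]
        )
        if bh_adjust:
            pvals = stats.false_discovery_control(pvals, method="bh")
        pm[iu] = pvals
        pm.T[iu] = pvals
        out[key] = pm
    return out


# ---------------------------------------------------------------------------
# Cooperativity
# ---------------------------------------------------------------------------

def save_heatmap(matrix: np.ndarray, path, title: str = "",
                 cmap: str = "RdBu_r", symmetric: bool = True) -> None:
    """Render a barcode-by-barcode map as a PNG heatmap (1-based axes)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = np.asarray(matrix, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    if symmetric:
        lim = np.nanmax(np.abs(m)) or 1.0
        im = ax.imshow(m, cmap=cmap, vmin=-lim, vmax=lim, origin="upper",
                       extent=(0.5, m.shape[1] + 0.5, m.shape[0] + 0.5, 0.5))
    else:
        im = ax.imshow(m, cmap="viridis", origin="upper",
                       extent=(0.5, m.shape[1] + 0.5, m.shape[0] + 0.5, 0.5))
    ax.set_xlabel("barcode")
    ax.set_ylabel("barcode")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.85)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


@dataclass
class CooperativityMap:
    avg_cooccurrence: np.ndarray  # (B, B), NaN where no cell is extreme
    pvalues: np.ndarray | None
    median_distance: np.ndarray | None
    percentile_threshold: float
    side: str
    n_cells: int = 0
    extreme_counts: np.ndarray = field(default=None)


def _extreme_matrix(
    attributions: np.ndarray, labels: np.ndarray, side: str, percentile: float
):
    """Boolean (n_side_cells, B*B) matrix of per-entry attribution extremeness.

    The percentile cutoffs are computed per entry across the WHOLE
    population (both classes); the returned rows are restricted to the
    requested side's cells. "Extreme" means above the cutoff for the ON
    side and below the mirrored cutoff for the OFF side.
    """
    if side not in ("on", "off"):
        raise InterpretError("side must be 'on' or 'off'")
    if not 0.0 < percentile < 100.0:
        raise InterpretError("percentile must be in (0, 100)")
    a = np.asarray(attributions)
    y = np.asarray(labels)
    cls = 1 if side == "on" else 0
    sub = a[y == cls]
    if len(sub) < 2:
        raise InterpretError(f"need >=2 cells in the {side} class")
    B = a.shape[-1]
    flat_all = a.reshape(len(a), B * B)
    flat_sub = sub.reshape(len(sub), B * B)
    if side == "on":
        cuts = np.percentile(flat_all, percentile, axis=0)
        return flat_sub > cuts, sub
    cuts = np.percentile(flat_all, 100.0 - percentile, axis=0)
    return flat_sub < cuts, sub


def pairwise_cooccurrence(
    attributions: np.ndarray,
    labels: np.ndarray,
    entry: tuple[int, int],
    side: str = "on",
    percentile: float = 99.0,
) -> np.ndarray:
    """Co-occurrence map anchored at one entry (a,b).

    Over the cells in which ``entry`` (0-based (row, col)) is attribution-
    extreme, the returned (B,B) map gives for every other entry (c,d) the
    fraction of those cells in which (c,d) is also extreme — the "punctum"
    view of one candidate hub interaction. NaN if ``entry`` is never extreme.
    """
    E, sub = _extreme_matrix(attributions, labels, side, percentile)
    B = sub.shape[-1]
    a = entry[0] * B + entry[1]
    anchor = E[:, a]
    if anchor.sum() == 0:
        return np.full((B, B), np.nan)
    freq = E[anchor].mean(axis=0).reshape(B, B)
    return freq


def cooperativity_map(
    attributions: np.ndarray,
    labels: np.ndarray,
    side: str = "on",
    percentile: float = 99.0,
    raw_matrices: np.ndarray | None = None,
    n_permutations: int = 200,
    seed: int = 0,
) -> CooperativityMap:
    """Average frequency of joint attribution-extremeness with other entries.

    An entry is "extreme" in a cell when its attribution is beyond its own
    per-entry population percentile (above for ON-side, below the mirrored
    percentile for OFF-side). For entry (a,b): over the cells where (a,b) is
    extreme, the co-occurrence with every other entry (c,d) is the fraction
    of those cells in which (c,d) is also extreme; the map stores the mean
    over all (c,d) != (a,b). Entries never extreme are NaN-masked.

    p-values come from a permutation null that shuffles each entry's
    extreme-cell assignment independently across cells (destroying within-
    cell co-occurrence, preserving per-entry rates).
    """
    E, sub = _extreme_matrix(attributions, labels, side, percentile)
    n = len(sub)
    B = sub.shape[-1]

    def _avg_cooc(E: np.ndarray) -> np.ndarray:
        counts = E.sum(axis=0).astype(float)  # per-entry extreme cells
        s = E.sum(axis=1).astype(float)  # per-cell extreme entries
        num = E.T @ s  # sum over cells of s_n where entry extreme
        M = E.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            val = (num - counts) / ((M - 1) * counts)
        val[counts == 0] = np.nan
        return val

    obs = _avg_cooc(E)
    pvals = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(E.shape[1])
        valid = np.zeros(E.shape[1])
        for _ in range(n_permutations):
            perm = np.argsort(rng.random(E.shape), axis=0)
            Ep = np.take_along_axis(E, perm, axis=0)
            null = _avg_cooc(Ep)
            ok = ~np.isnan(null) & ~np.isnan(obs)
            exceed[ok] += null[ok] >= obs[ok]
            valid[ok] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (exceed + 1.0) / (valid + 1.0)
        p[np.isnan(obs)] = np.nan
        pvals = p.reshape(B, B)

    med = None
    if raw_matrices is not None:
        cls = 1 if side == "on" else 0
        d = np.asarray(raw_matrices, dtype=float)[np.asarray(labels) == cls]
        d = d.reshape(n, B * B)
        with np.errstate(invalid="ignore"):
            masked = np.where(E, d, np.nan)
            med = np.nanmedian(masked, axis=0).reshape(B, B)

    return CooperativityMap(
        avg_cooccurrence=obs.reshape(B, B),
        pvalues=pvals,
        median_distance=med,
        percentile_threshold=percentile,
        side=side,
        n_cells=n,
        extreme_counts=E.sum(axis=0).reshape(B, B),
    )
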