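"""Ground-truth expression rules for simulated conformations.

Four regulatory rules assign binary ON/OFF nascent-transcription labels to a
polymer ensemble:

* **binary contact** — rank all examples by the enhancer–promoter distance
  (monomers 20 and 40, 1-based) and mark the closest 30% ON;
* **compaction** — rank by the median of all pairwise distances and mark the
  30% most decompacted (largest median) ON;
* **hierarchical** (independent or cooperative) — one promoter (20), two
  enhancers (5, 35) and one dominant silencer (45) act through contact
  indicators at a calibrated threshold, with stochastic activation and
  silencing probabilities.

Label noise models non-structural determinants of transcription: each
example first has a ``random_fraction`` chance of receiving a fair-coin
label and never consulting the rule. The label-shuffle control permutes
labels to destroy any structure–label correspondence while preserving class
counts.

Element indices in the rule dataclasses are 1-based barcode numbers,
matching the "monomer 20 / monomer 40" convention used everywhere outside
in-memory arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tracenet.polymer_sim import ConformationEnsemble


class LabelingError(ValueError):
    pass


@dataclass
class ContactRule:
    enhancer_index: int = 20  # 1-based barcode numbers
    promoter_index: int = 40
    on_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.enhancer_index == self.promoter_index:
            raise LabelingError("enhancer and promoter indices must differ")
        if not 0.0 < self.on_fraction < 1.0:
            raise LabelingError("on_fraction must be in (0, 1)")


@dataclass
class CompactionRule:
    on_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 < self.on_fraction < 1.0:
            raise LabelingError("on_fraction must be in (0, 1)")


@dataclass
class HierarchicalRule:
    promoter: int = 20  # 1-based
    enhancers: tuple[int, int] = (5, 35)
    silencer: int = 45
    contact_threshold: float | None = None  # nm; set by calibration
    p_silence: float = 0.8
    p_activate_single: float = 0.8  # 0.1 in the cooperative variant
    p_activate_both: float = 0.8  # used only when cooperative=True
    cooperative: bool = False
    # When both enhancers contact in the independent variant: "independent"
    # draws one activation attempt per contacting enhancer (ON if any
    # succeeds); "single" makes one draw at p_activate_single.
    dual_contact_semantics: str = "independent"

    def __post_init__(self) -> None:
        ids = (self.promoter, *self.enhancers, self.silencer)
        if len(set(ids)) != len(ids):
            raise LabelingError("regulatory element indices must be distinct")
        for p in (self.p_silence, self.p_activate_single, self.p_activate_both):
            if not 0.0 <= p <= 1.0:
                raise LabelingError("probabilities must lie in [0, 1]")
        if self.dual_contact_semantics not in ("independent", "single"):
            raise LabelingError("dual_contact_semantics must be independent|single")

    @classmethod
    def cooperative_default(cls, **kw) -> "HierarchicalRule":
        kw.setdefault("p_activate_single", 0.1)
        kw.setdefault("p_activate_both", 0.8)
        kw.setdefault("cooperative", True)
        return cls(**kw)


@dataclass
class NoiseSpec:
    """Fraction of examples labeled by a fair coin instead of the rule."""

    random_fraction: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 <= self.random_fraction <= 1.0:
            raise LabelingError("random_fraction must lie in [0, 1]")


NO_NOISE = NoiseSpec(random_fraction=0.0)


# ---------------------------------------------------------------------------
# Rule statistics
# ---------------------------------------------------------------------------

def _coords(ensemble) -> np.ndarray:
    if isinstance(ensemble, ConformationEnsemble):
        return ensemble.coords()
    return np.asarray(ensemble, dtype=float)  # (N, B, 3)


def pair_distances(ensemble, i: int, j: int) -> np.ndarray:
    """Per-example distance between 1-based barcodes i and j (nm)."""
    c = _coords(ensemble)
    return np.linalg.norm(c[:, i - 1] - c[:, j - 1], axis=-1)


def median_pairwise_distance(ensemble) -> np.ndarray:
    """Per-example median over all B(B-1)/2 pairwise distances (nm)."""
    c = _coords(ensemble)
    d = np.linalg.norm(c[:, :, None, :] - c[:, None, :, :], axis=-1)
    iu = np.triu_indices(c.shape[1], k=1)
    return np.median(d[:, iu[0], iu[1]], axis=1)


def _rank_labels(
    statistic: np.ndarray,
    on_fraction: float,
    noise: NoiseSpec,
    rng: np.random.Generator,
    smallest_on: bool,
) -> np.ndarray:
    """Noise draw first, then rank the full ensemble and threshold by count.

    Ranking happens over ALL examples (noisy ones included) so the rule's
    cutoff reflects the population; noisy examples then keep their coin flip.
    Ties are broken by example index (stable sort).
    """
    n = len(statistic)
    order = np.argsort(statistic, kind="stable")
    if not smallest_on:
        order = np.argsort(-statistic, kind="stable")
    n_on = int(round(on_fraction * n))
    rule_labels = np.zeros(n, dtype=np.int8)
    rule_labels[order[:n_on]] = 1
    noisy = rng.random(n) < noise.random_fraction
    coin = (rng.random(n) < 0.5).astype(np.int8)
    return np.where(noisy, coin, rule_labels)


def label_binary_contact(
    ensemble,
    rule: ContactRule | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Enhancer–promoter contact rule: closest ``on_fraction`` of E-P distances are ON."""
    rule = rule or ContactRule()
    noise = noise or NoiseSpec()
    d = pair_distances(ensemble, rule.enhancer_index, rule.promoter_index)
    rng = np.random.default_rng(seed)
    return _rank_labels(d, rule.on_fraction, noise, rng, smallest_on=True)


def label_compaction(
    ensemble,
    rule: CompactionRule | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Compaction rule: the ``on_fraction`` most decompacted examples are ON."""
    rule = rule or CompactionRule()
    noise = noise or NoiseSpec()
    med = median_pairwise_distance(ensemble)
    rng = np.random.default_rng(seed)
    return _rank_labels(med, rule.on_fraction, noise, rng, smallest_on=False)


# ---------------------------------------------------------------------------
# Hierarchical rule
# ---------------------------------------------------------------------------

def _expected_on_probability(
    e1: np.ndarray, e2: np.ndarray, s: np.ndarray, rule: HierarchicalRule
) -> np.ndarray:
    """Closed-form P(ON) per example given boolean contact indicators."""
    if rule.cooperative:
        act = np.where(
            e1 & e2,
            rule.p_activate_both,
            np.where(e1 | e2, rule.p_activate_single, 0.0),
        )
    elif rule.dual_contact_semantics == "independent":
        n_contact = e1.astype(int) + e2.astype(int)
        act = 1.0 - (1.0 - rule.p_activate_single) ** n_contact
    else:
        act = np.where(e1 | e2, rule.p_activate_single, 0.0)
    return np.where(s, (1.0 - rule.p_silence) * act, act)


def _contacts(ensemble, rule: HierarchicalRule, threshold: float):
    e1 = pair_distances(ensemble, rule.enhancers[0], rule.promoter) <= threshold
    e2 = pair_distances(ensemble, rule.enhancers[1], rule.promoter) <= threshold
    s = pair_distances(ensemble, rule.silencer, rule.promoter) <= threshold
    return e1, e2, s


def calibrate_contact_threshold(
    ensemble,
    target_on_fraction: float = 0.30,
    rule: HierarchicalRule | None = None,
    tolerance: float = 0.03,
) -> float:
    """Contact threshold (nm) whose expected ON fraction matches the target.

    Uses the closed-form expected ON probability given the contact indicators
    and bisects over quantiles of the pooled element–promoter distances on
    the rising branch of the (non-monotone) expected-ON curve. Raises if no
    threshold reaches the target within tolerance, reporting the achievable
    range.
    """
    rule = rule or HierarchicalRule()
    d_e1 = pair_distances(ensemble, rule.enhancers[0], rule.promoter)
    d_e2 = pair_distances(ensemble, rule.enhancers[1], rule.promoter)
    d_s = pair_distances(ensemble, rule.silencer, rule.promoter)
    pooled = np.sort(np.concatenate([d_e1, d_e2, d_s]))

    def expected_on(threshold: float) -> float:
        p = _expected_on_probability(
            d_e1 <= threshold, d_e2 <= threshold, d_s <= threshold, rule
        )
        return float(p.mean())

    qs = np.linspace(0.0, 1.0, 201)
    ts = np.quantile(pooled, qs)
    vals = np.array([expected_on(t) for t in ts])
    feasible = vals >= target_on_fraction
    if not feasible.any():
        raise LabelingError(
            "target ON fraction unreachable: achievable range is "
            f"[{vals.min():.3f}, {vals.max():.3f}]"
        )
    # first grid crossing on the rising branch, refined by bisection
    k = int(np.argmax(feasible))
    if k == 0:
        return float(ts[0])
    lo, hi = ts[k - 1], ts[k]
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if expected_on(mid) >= target_on_fraction:
            hi = mid
        else:
            lo = mid
    t = float(hi)
    if abs(expected_on(t) - target_on_fraction) > tolerance:
        raise LabelingError(
            f"calibration landed at expected ON {expected_on(t):.3f}, "
            f"outside ±{tolerance} of target {target_on_fraction}"
        )
    return t


def label_hierarchical(
    ensemble, rule: HierarchicalRule, seed: int = 0
) -> np.ndarray:
    """Hierarchical enhancer/silencer rule with a dominant stochastic silencer.

    Per example: silencer–promoter contact turns the gene OFF with
    probability ``p_silence`` regardless of enhancers; surviving examples
    run the enhancer logic (independent draws per contacting enhancer, or
    the cooperative one-/both-contact probabilities); no contact means OFF.
    """
    if rule.contact_threshold is None:
        raise LabelingError(
            "rule.contact_threshold is unset; run calibrate_contact_threshold"
        )
    e1, e2, s = _contacts(ensemble, rule, rule.contact_threshold)
    rng = np.random.default_rng(seed)
    n = len(e1)
    silenced = s & (rng.random(n) < rule.p_silence)
    if rule.cooperative:
        p_act = np.where(
            e1 & e2,
            rule.p_activate_both,
            np.where(e1 | e2, rule.p_activate_single, 0.0),
        )
        active = rng.random(n) < p_act
    elif rule.dual_contact_semantics == "independent":
        a1 = e1 & (rng.random(n) < rule.p_activate_single)
        a2 = e2 & (rng.random(n) < rule.p_activate_single)
        active = a1 | a2
    else:
        active = (e1 | e2) & (rng.random(n) < rule.p_activate_single)
    return (active & ~silenced).astype(np.int8)


# ---------------------------------------------------------------------------
# Controls and theory
# ---------------------------------------------------------------------------

def shuffle_labels(labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Uniform random permutation of the label vector (class counts preserved)."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise LabelingError("cannot shuffle an empty label vector")
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(len(labels))]


def expected_on_fraction(noise_fraction: float, rule_on_fraction: float) -> float:
    """E[ON] under label noise f and rank rule q: f/2 + (1-f)·q."""
    return noise_fraction / 2.0 + (1.0 - noise_fraction) * rule_on_fraction


def bayes_optimal_auc(noise_fraction: float = 0.5, on_fraction: float = 0.3) -> float:
    """AUC ceiling for rank-rule tasks under label noise.

    The only label-relevant information in an example is the binary rule
    indicator R (e.g. "E-P distance in the closest 30%"), so the optimal
    score takes two values and the AUC follows from the two conditional
    probabilities P(R=1 | label) with the standard tie correction. At
    noise 0.5 / ON fraction 0.3 this evaluates to ≈0.719: no classifier can
    beat it on held-out data except by chance.
    """
    f, q = noise_fraction, on_fraction
    p_on = f / 2.0 + (1.0 - f) * q
    p_r1_on = q * (f / 2.0 + (1.0 - f)) / p_on
    p_r1_off = q * (f / 2.0) / (1.0 - p_on)
    # AUC = P(score_on > score_off) + 0.5 P(tie)
    return p_r1_on * (1.0 - p_r1_off) + 0.5 * (
        p_r1_on * p_r1_off + (1.0 - p_r1_on) * (1.0 - p_r1_off)
    )
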