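"""Confined bead-spring polymer ensembles.

Generates heterogeneous conformations of a 52-monomer chromatin-like polymer:
harmonic bonds between sequential monomers, a capped soft-core repulsion at
close range (no self-attraction), and a harmonic spherical confinement that
plays the role of nuclear density. Dynamics are overdamped Langevin
(Brownian) updates; many chains are integrated simultaneously as one
vectorized batch, and each recorded frame of each chain is one example, so an
ensemble of ``n_chains x frames_per_chain`` conformations mirrors how tracing
experiments treat every imaged cell as an independent sample. Consecutive
frames of one chain are separated by ``steps_per_frame`` integration steps
and may be autocorrelated.

Simulation units are dimensionless with bond rest length 1; ``nm_per_unit``
maps them onto nanometres so that physical contact thresholds (e.g. the
150 nm enhancer–promoter proximity criterion) are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from tracenet.trace_data import PolymerTrace


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    n_monomers: int = 52
    n_chains: int = 500
    frames_per_chain: int = 100
    steps_per_frame: int = 100
    bond_rest_length: float = 1.0
    bond_stiffness: float = 40.0
    bend_stiffness: float = 4.0  # Kratky-Porod; persistence of a few barcodes
    repulsion_radius: float = 0.8
    repulsion_strength: float = 20.0
    confinement_radius: float = 4.0
    confinement_stiffness: float = 10.0
    step_size: float = 0.005  # integrator dt (friction folded in)
    thermal_scale: float = 1.0  # kT
    burn_in_steps: int | None = None  # default 20 x steps_per_frame
    nm_per_unit: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_monomers", "n_chains", "frames_per_chain", "steps_per_frame"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        if self.confinement_radius <= self.bond_rest_length:
            raise SimulationError("confinement_radius must exceed bond_rest_length")

    @property
    def effective_burn_in(self) -> int:
        if self.burn_in_steps is not None:
            return self.burn_in_steps
        # long enough for the bending term to relax the floppy initial walk
        return 20 * self.steps_per_frame


@dataclass
class ConformationEnsemble:
    """Complete polymer conformations plus (chain, frame) provenance."""

    traces: list  # list[PolymerTrace], coordinates in nm
    provenance: np.ndarray  # (N, 2) int: chain_id, frame_id
    config: SimulationConfig = field(default_factory=SimulationConfig)

    def __len__(self) -> int:
        return len(self.traces)

    def coords(self) -> np.ndarray:
        """(N, B, 3) coordinate stack in nm."""
        return np.stack([t.coords for t in self.traces])

    def thin(self, every: int) -> "ConformationEnsemble":
        """Keep every ``every``-th frame of each chain (autocorrelation control)."""
        keep = self.provenance[:, 1] % every == 0
        return ConformationEnsemble(
            traces=[t for t, k in zip(self.traces, keep) if k],
            provenance=self.provenance[keep],
            config=self.config,
        )


@njit(cache=True, fastmath=True)
def _integrate(x, noise, dt, k_bond, r0, k_bend, r_rep, k_rep, r_conf, k_conf):
    """In-place Brownian updates; ``noise`` is (n_steps, C, B, 3), pre-scaled.

    Per step and chain: harmonic bond forces, capped soft-core repulsion
    (magnitude k_rep*(1 - r/r_rep) inside the radius, zero outside), harmonic
    radial confinement beyond r_conf, then the overdamped Euler update.
    """
    n_steps = noise.shape[0]
    C, B = x.shape[0], x.shape[1]
    f = np.empty((B, 3))
    r_rep2 = r_rep * r_rep
    for s in range(n_steps):
        for c in range(C):
            xc = x[c]
            for b in range(B):
                for k in range(3):
                    f[b, k] = 0.0
            for b in range(B - 1):
                d0 = xc[b + 1, 0] - xc[b, 0]
                d1 = xc[b + 1, 1] - xc[b, 1]
                d2 = xc[b + 1, 2] - xc[b, 2]
                r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
                if r < 1e-12:
                    continue
                coef = k_bond * (r - r0) / r
                f[b, 0] += coef * d0
                f[b, 1] += coef * d1
                f[b, 2] += coef * d2
                f[b + 1, 0] -= coef * d0
                f[b + 1, 1] -= coef * d1
                f[b + 1, 2] -= coef * d2
            # Kratky-Porod bending: U = k_bend * (1 - cos theta) per triplet
            if k_bend > 0.0:
                for b in range(1, B - 1):
                    u0 = xc[b, 0] - xc[b - 1, 0]
                    u1 = xc[b, 1] - xc[b - 1, 1]
                    u2 = xc[b, 2] - xc[b - 1, 2]
                    v0 = xc[b + 1, 0] - xc[b, 0]
                    v1 = xc[b + 1, 1] - xc[b, 1]
                    v2 = xc[b + 1, 2] - xc[b, 2]
                    lu = np.sqrt(u0 * u0 + u1 * u1 + u2 * u2)
                    lv = np.sqrt(v0 * v0 + v1 * v1 + v2 * v2)
                    if lu < 1e-9 or lv < 1e-9:
                        continue
                    dot = u0 * v0 + u1 * v1 + u2 * v2
                    inv = 1.0 / (lu * lv)
                    # a = d(cos)/du, bb = d(cos)/dv
                    a0 = v0 * inv - dot * u0 / (lu * lu * lu * lv)
                    a1 = v1 * inv - dot * u1 / (lu * lu * lu * lv)
                    a2 = v2 * inv - dot * u2 / (lu * lu * lu * lv)
                    b0 = u0 * inv - dot * v0 / (lu * lv * lv * lv)
                    b1 = u1 * inv - dot * v1 / (lu * lv * lv * lv)
                    b2 = u2 * inv - dot * v2 / (lu * lv * lv * lv)
                    f[b - 1, 0] -= k_bend * a0
                    f[b - 1, 1] -= k_bend * a1
                    f[b - 1, 2] -= k_bend * a2
                    f[b, 0] += k_bend * (a0 - b0)
                    f[b, 1] += k_bend * (a1 - b1)
                    f[b, 2] += k_bend * (a2 - b2)
                    f[b + 1, 0] += k_bend * b0
                    f[b + 1, 1] += k_bend * b1
                    f[b + 1, 2] += k_bend * b2
            for i in range(B - 1):
                for j in range(i + 1, B):
                    d0 = xc[i, 0] - xc[j, 0]
                    d1 = xc[i, 1] - xc[j, 1]
                    d2 = xc[i, 2] - xc[j, 2]
                    rr = d0 * d0 + d1 * d1 + d2 * d2
                    if rr < r_rep2:
                        r = np.sqrt(rr)
                        coef = k_rep * (1.0 / max(r, 1e-9) - 1.0 / r_rep)
                        f[i, 0] += coef * d0
                        f[i, 1] += coef * d1
                        f[i, 2] += coef * d2
                        f[j, 0] -= coef * d0
                        f[j, 1] -= coef * d1
                        f[j, 2] -= coef * d2
            for b in range(B):
                rad = np.sqrt(
                    xc[b, 0] ** 2 + xc[b, 1] ** 2 + xc[b, 2] ** 2
                )
                if rad > r_conf:
                    coef = k_conf * (rad - r_conf) / rad
                    f[b, 0] -= coef * xc[b, 0]
                    f[b, 1] -= coef * xc[b, 1]
                    f[b, 2] -= coef * xc[b, 2]
                for k in range(3):
                    xc[b, k] += dt * f[b, k] + noise[s, c, b, k]


def _initial_chains(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Random-walk initialization folded inside the confinement sphere."""
    steps = rng.normal(size=(cfg.n_chains, cfg.n_monomers - 1, 3))
    steps *= cfg.bond_rest_length / np.linalg.norm(steps, axis=-1, keepdims=True)
    x = np.concatenate(
        [np.zeros((cfg.n_chains, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    x -= x.mean(axis=1, keepdims=True)
    # pull any excursions back inside the sphere
    rad = np.linalg.norm(x, axis=-1, keepdims=True)
    shrink = np.minimum(1.0, 0.95 * cfg.confinement_radius / np.maximum(rad, 1e-12))
    return x * shrink


def simulate_ensemble(config: SimulationConfig) -> ConformationEnsemble:
    """Run the Brownian dynamics and record ``n_chains x frames_per_chain`` frames.

    Deterministic for a fixed ``config.seed``. Raises if the trajectory
    becomes non-finite (integration instability) — reduce ``step_size`` or
    stiffnesses in that case.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    x = _initial_chains(cfg, rng)
    dt = cfg.step_size
    noise_scale = np.sqrt(2.0 * cfg.thermal_scale * dt)

    def step(x: np.ndarray, n: int) -> np.ndarray:
        # noise drawn in blocks keeps the stream deterministic per seed
        for start in range(0, n, 50):
            block = min(50, n - start)
            noise = noise_scale * rng.normal(size=(block, *x.shape))
            _integrate(
                x,
                noise,
                dt,
                cfg.bond_stiffness,
                cfg.bond_rest_length,
                cfg.bend_stiffness,
                cfg.repulsion_radius,
                cfg.repulsion_strength,
                cfg.confinement_radius,
                cfg.confinement_stiffness,
            )
        return x

    x = step(x, cfg.effective_burn_in)
    frames = np.empty(
        (cfg.n_chains, cfg.frames_per_chain, cfg.n_monomers, 3), dtype=float
    )
    for f_id in range(cfg.frames_per_chain):
        x = step(x, cfg.steps_per_frame)
        if not np.isfinite(x).all():
            raise SimulationError(
                f"non-finite coordinates at frame {f_id}; integration unstable"
            )
        frames[:, f_id] = x

    traces = []
    prov = np.empty((cfg.n_chains * cfg.frames_per_chain, 2), dtype=int)
    k = 0
    for c_id in range(cfg.n_chains):
        for f_id in range(cfg.frames_per_chain):
            traces.append(
                PolymerTrace(
                    cell_id=f"sim-c{c_id}-f{f_id}",
                    coords=frames[c_id, f_id] * cfg.nm_per_unit,
                    meta={"chain": c_id, "frame": f_id},
                )
            )
            prov[k] = (c_id, f_id)
            k += 1
    return ConformationEnsemble(traces=traces, provenance=prov, config=cfg)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def radius_of_gyration(coords: np.ndarray) -> np.ndarray:
    """Rg per conformation for an (N, B, 3) (or (B, 3)) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    centered = coords - coords.mean(axis=1, keepdims=True)
    rg = np.sqrt((centered**2).sum(axis=-1).mean(axis=1))
    return rg[0] if single else rg


def ensemble_diagnostics(
    ensemble: ConformationEnsemble, contact_threshold_nm: float = 150.0
) -> dict:
    """Summary statistics: bond lengths, Rg distribution, contact-frequency map.

    The contact map uses the given physical threshold; for a sane polymer
    ensemble contact frequency decays on average with genomic separation.
    """
    if len(ensemble) == 0:
        raise SimulationError("empty ensemble")
    coords = ensemble.coords()
    bonds = np.linalg.norm(np.diff(coords, axis=1), axis=-1)
    d = np.linalg.norm(coords[:, :, None, :] - coords[:, None, :, :], axis=-1)
    contact = (d <= contact_threshold_nm).mean(axis=0)
    B = coords.shape[1]
    sep = np.abs(np.arange(B)[:, None] - np.arange(B)[None, :])
    by_sep = np.array(
        [contact[sep == s].mean() for s in range(1, B)]
    )
    return {
        "n_examples": len(ensemble),
        "mean_bond_length_nm": float(bonds.mean()),
        "bond_length_std_nm": float(bonds.std()),
        "rg_nm": radius_of_gyration(coords),
        "contact_frequency": contact,
        "contact_by_separation": by_sep,
        "max_radius_nm": float(
            np.linalg.norm(coords - coords.mean(axis=1, keepdims=True), axis=-1).max()
        ),
    }


def boltzmann_mean_bond_length(
    stiffness: float, rest_length: float = 1.0, kT: float = 1.0
) -> float:
    """Equilibrium mean bond length by 1-D quadrature over P(r) ∝ r² e^{-k(r-r0)²/2kT}.

    Independent closed-form check for the simulated bond statistics.
    """
    sigma = np.sqrt(kT / stiffness)
    r = np.linspace(max(1e-9, rest_length - 8 * sigma), rest_length + 8 * sigma, 20001)
    w = r**2 * np.exp(-stiffness * (r - rest_length) ** 2 / (2.0 * kT))
    return float(np.trapezoid(r * w, r) / np.trapezoid(w, r))


def fast_config(
    n_examples: int = 1000,
    frames_per_chain: int = 100,
    steps_per_frame: int = 50,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """A desk-scale configuration producing ``n_examples`` conformations."""
    n_chains = max(1, int(np.ceil(n_examples / frames_per_chain)))
    return SimulationConfig(
        n_chains=n_chains,
        frames_per_chain=frames_per_chain,
        steps_per_frame=steps_per_frame,
        seed=seed,
        **overrides,
    )
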