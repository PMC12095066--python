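"""Synthetic genotypes and genotype-dependent low-rank trait dynamics.

The generator realizes the data-generating assumption the whole method
rests on: each genotype's latent trait state advances by a time-invariant
linear operator, x_{t+1} = A(g) x_t, and the operator's low-rank factors
depend additively on the genotype's markers.

Construction, per population:

* dosages ~ Binomial(2, freq) per marker, freq uniform on a MAF range;
* a shared orthonormal mode basis Φ0 (p x r_true), so that canonical factor
  entries are genuinely comparable across genotypes (the regime in which
  treating matrix entries as traits is meaningful); an optional per-line
  basis rotation lets tests probe violation of that assumption;
* per line a reduced operator R(g) whose entries are
  base + (centered dosages)·(sparse effects) + residual, with the realized
  genetic/residual variance ratio matched exactly to the target entry
  heritability; eigenvalues kept inside a spectral interval;
* latent states advance through *every* calendar day (including unmeasured
  gap days); observations are latent values plus i.i.d. Gaussian noise at
  the measured days only.

Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import GenotypeMatrix, TraitTensor, infer_blocks

__all__ = [
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_operator_family",
    "simulate_trajectories",
    "make_benchmark_scenario",
    "gapped_days",
]


@dataclass
class SyntheticTruth:
    genotypes: GenotypeMatrix
    true_operators: dict[str, np.ndarray]         # per line, p x p
    true_reduced: dict[str, np.ndarray]           # per line, r_true x r_true
    true_mode_basis: np.ndarray                   # p x r_true
    true_entry_effects: dict[tuple[int, int], np.ndarray]
    entry_h2: float
    r_true: int
    trajectory_noise_sd: float = float("nan")
    x1_coefficients: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0


def gapped_days(n_blocks: int = 5, block_len: int = 5, start: int = 15,
                gap: int = 2) -> np.ndarray:
    """Calendar days of a blocked design: ``n_blocks`` runs of ``block_len``
    consecutive days separated by ``gap`` unmeasured days."""
    days = []
    d = start
    for _ in range(n_blocks):
        days.extend(range(d, d + block_len))
        d += block_len + gap
    return np.array(days)


def simulate_genotypes(k: int, m: int, maf_range: tuple[float, float] = (0.05, 0.5),
                       seed: int = 0) -> GenotypeMatrix:
    """Independent biallelic markers: dosages ~ Binomial(2, freq) per line.

    Markers whose realized MAF falls below 0.01 are redrawn.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if k < 2 or m < 1:
        raise ValueError("need k >= 2 lines and m >= 1 markers")
    rng = np.random.default_rng(seed)
    dosages = np.empty((k, m), dtype=np.int64)
    for j in range(m):
        for _ in range(1000):
            freq = rng.uniform(lo, hi)
            col = rng.binomial(2, freq, size=k)
            p = col.mean() / 2.0
            if min(p, 1 - p) >= 0.01:
                break
        else:
            raise ValueError("could not draw a polymorphic marker; "
                             "maf_range is infeasible for this k")
        dosages[:, j] = col
    line_ids = [f"L{i:04d}" for i in range(k)]
    marker_ids = [f"M{j:05d}" for j in range(m)]
    return GenotypeMatrix(line_ids, marker_ids, dosages)


def _heritable_column(rng: np.random.Generator, Wc: np.ndarray, h2: float,
                      scale: float, n_causal: int) -> tuple[np.ndarray, np.ndarray]:
    """A k-vector with realized genetic variance fraction exactly ``h2``.

    Genetic part: sparse marker effects on the centered dosages, rescaled to
    sd = scale*sqrt(h2); residual rescaled to sd = scale*sqrt(1-h2).
    """
    k, m = Wc.shape
    n_causal = min(n_causal, m)
    effects = np.zeros(m)
    z = np.zeros(k)
    if h2 > 0:
        causal = rng.choice(m, size=n_causal, replace=False)
        effects[causal] = rng.normal(size=n_causal)
        z = Wc @ effects
        sd = z.std()
        if sd == 0:
            raise ValueError("degenerate genetic values; need more polymorphic markers")
        f = scale * np.sqrt(h2) / sd
        z = z * f
        effects = effects * f
    e = np.zeros(k)
    if h2 < 1:
        e = rng.normal(size=k)
        e = (e - e.mean()) / e.std() * scale * np.sqrt(1.0 - h2)
    return z + e, effects


def simulate_operator_family(
    G: GenotypeMatrix,
    p: int,
    r_true: int = 2,
    entry_h2: float = 0.5,
    spectral_interval: tuple[float, float] = (0.7, 1.08),
    seed: int = 0,
    n_causal: int = 20,
    effect_scale: float = 0.03,
    rotation_sd: float = 0.0,
) -> SyntheticTruth:
    """Genotype-dependent operators A(g) = Φ0 R(g) Φ0ᵀ.

    R(g) is built around a base reduced operator with well-separated
    eigenvalue moduli spread across ``spectral_interval``; each entry gets a
    genotype term and a residual with realized variance ratio exactly
    ``entry_h2``. Lines whose spectral radius leaves the interval are
    rescaled back into it. ``rotation_sd`` > 0 applies a small per-line
    rotation to the mode basis (breaking exact cross-line comparability).
    """
    if not 1 <= r_true <= p:
        raise ValueError("need 1 <= r_true <= p")
    if not 0 <= entry_h2 <= 1:
        raise ValueError("entry_h2 must be in [0, 1]")
    lo, hi = spectral_interval
    rng = np.random.default_rng(seed)
    k = G.n_lines
    Wc = G.dosages - G.dosages.mean(axis=0)
    if entry_h2 > 0 and G.n_markers < 1:
        raise ValueError("heritable entries need at least one marker")

    Phi0 = np.linalg.qr(rng.normal(size=(p, r_true)))[0]
    # base eigenvalues well inside the interval with separated moduli, so
    # small genetic perturbations neither leave the interval nor collide
    if r_true > 1:
        base_diag = np.linspace(lo + 0.8 * (hi - lo), lo + 0.35 * (hi - lo), r_true)
    else:
        base_diag = np.array([(lo + hi) / 2])
    R_base = np.diag(base_diag)

    deviations = np.zeros((k, r_true, r_true))
    effects: dict[tuple[int, int], np.ndarray] = {}
    for i in range(r_true):
        for j in range(r_true):
            col, eff = _heritable_column(rng, Wc, entry_h2, effect_scale, n_causal)
            deviations[:, i, j] = col
            effects[(i, j)] = eff

    true_reduced: dict[str, np.ndarray] = {}
    true_ops: dict[str, np.ndarray] = {}
    for li, line in enumerate(G.line_ids):
        R = R_base + deviations[li]
        rho = float(np.max(np.abs(np.linalg.eigvals(R))))
        if rho > hi:
            R = R * (hi / rho)
        elif rho < lo and rho > 0:
            R = R * (lo / rho)
        basis = Phi0
        if rotation_sd > 0:
            S = rng.normal(scale=rotation_sd, size=(p, p))
            basis = np.linalg.qr(Phi0 + (S - S.T) @ Phi0)[0]
        true_reduced[line] = R
        true_ops[line] = basis @ R @ basis.T
    return SyntheticTruth(
        genotypes=G, true_operators=true_ops, true_reduced=true_reduced,
        true_mode_basis=Phi0, true_entry_effects=effects, entry_h2=entry_h2,
        r_true=r_true, seed=seed,
    )


def simulate_trajectories(
    truth: SyntheticTruth,
    time_axis: np.ndarray,
    noise_sd: float = 0.0,
    x1_spec: dict | None = None,
    seed: int = 0,
) -> TraitTensor:
    """Observe the latent linear dynamics on a (possibly gapped) day axis.

    ``x1_spec`` controls the initial latent state x_1 = Φ0 c_1 with
    per-coefficient c_1 = base + genetic + noise:
    ``{"c_base": ..., "genetic_h2": ..., "genetic_sd": ..., "noise_sd": ...}``.
    The latent state advances by the line's true operator once per calendar
    day, including unmeasured gap days.
    """
    time_axis = np.asarray(time_axis)
    blocks = infer_blocks(time_axis)
    G = truth.genotypes
    k = G.n_lines
    r = truth.r_true
    p = truth.true_mode_basis.shape[0]
    spec = {"c_base": None, "genetic_h2": truth.entry_h2, "genetic_sd": 0.05,
            "noise_sd": 0.02}
    spec.update(x1_spec or {})
    rng = np.random.default_rng(seed)
    c_base = spec["c_base"]
    if c_base is None:
        c_base = np.linspace(1.0, 0.6, r)
    c_base = np.broadcast_to(np.asarray(c_base, dtype=float), (r,))

    Wc = G.dosages - G.dosages.mean(axis=0)
    C1 = np.tile(c_base, (k, 1))
    for ci in range(r):
        if spec["genetic_sd"] > 0:
            col, _ = _heritable_column(rng, Wc, spec["genetic_h2"],
                                       spec["genetic_sd"], n_causal=20)
            C1[:, ci] += col
        if spec["noise_sd"] > 0:
            C1[:, ci] += rng.normal(scale=spec["noise_sd"], size=k)

    T = len(time_axis)
    values = np.empty((k, p, T))
    all_days = np.arange(time_axis[0], time_axis[-1] + 1)
    measured = np.isin(all_days, time_axis)
    for li, line in enumerate(G.line_ids):
        A = truth.true_operators[line]
        x = truth.true_mode_basis @ C1[li]
        col = 0
        for di, day in enumerate(all_days):
            if di > 0:
                x = A @ x
            if not np.isfinite(x).all():
                raise FloatingPointError(
                    f"line {line!r}: non-finite latent state at day {int(day)} "
                    "(unstable operator)"
                )
            if measured[di]:
                values[li, :, col] = x
                col += 1
        truth.x1_coefficients[line] = C1[li].copy()
    if noise_sd > 0:
        values = values + rng.normal(scale=noise_sd, size=values.shape)
    truth.trajectory_noise_sd = float(noise_sd)
    trait_ids = [f"trait{j:03d}" for j in range(p)]
    return TraitTensor(list(G.line_ids), trait_ids, time_axis, values,
                       [b.copy() for b in blocks])


_SCENARIOS = {
    # entry_h2, noise_sd, k, p, r_true, m, effect_scale, diag spread
    "perfect": dict(entry_h2=1.0, noise_sd=0.0, k=100, p=10, r_true=2, m=40,
                    effect_scale=0.005, spectral_interval=(0.70, 1.00),
                    x1_genetic_sd=0.02),
    "heritable": dict(entry_h2=0.5, noise_sd=0.05, k=300, p=20, r_true=2, m=1000,
                      effect_scale=0.03, spectral_interval=(0.70, 1.05),
                      x1_genetic_sd=0.3),
    # the null control removes *every* across-line information channel the
    # forecaster could exploit: markers carry no signal (entry_h2 = 0) and
    # the systematic initial-state spread is switched off, so line-to-line
    # differences are pure (unforecastable) noise. Any accuracy the pipeline
    # reports here is manufactured.
    "null": dict(entry_h2=0.0, noise_sd=0.05, k=300, p=20, r_true=2, m=1000,
                 effect_scale=0.03, spectral_interval=(0.70, 1.05),
                 x1_genetic_sd=0.0, x1_noise_sd=0.01),
    "maize_like": dict(entry_h2=0.3, noise_sd=0.05, k=330, p=50, r_true=2, m=2000,
                       effect_scale=0.03, spectral_interval=(0.70, 1.05),
                       x1_genetic_sd=0.3),
}


def make_benchmark_scenario(name: str, seed: int = 0
                            ) -> tuple[GenotypeMatrix, TraitTensor, SyntheticTruth]:
    """Preset populations for validation at desk scale.

    * ``perfect`` — noise-free dynamics and fully marker-determined
      operators: the limit where the pipeline must recover trajectories
      almost exactly.
    * ``heritable`` — moderately heritable operator entries (h² = 0.5) and
      5% trajectory noise on a 300-line, 20-trait population.
    * ``null`` — operators independent of the genotype: any apparent
      prediction accuracy is spurious.
    * ``maize_like`` — dimensions of a field-scale phenomics panel
      (330 lines, 50 traits, 25 timepoints in 5-day blocks).

    All scenarios use the blocked 25-day measurement design (5-day blocks
    separated by 2-day gaps, starting at day 15).
    """
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    cfg = _SCENARIOS[name]
    seeds = np.random.SeedSequence(seed).generate_state(3) % (2 ** 31)
    G = simulate_genotypes(cfg["k"], cfg["m"], seed=int(seeds[0]))
    truth = simulate_operator_family(
        G, p=cfg["p"], r_true=cfg["r_true"], entry_h2=cfg["entry_h2"],
        spectral_interval=cfg["spectral_interval"], seed=int(seeds[1]),
        effect_scale=cfg["effect_scale"],
    )
    x1_spec = {"genetic_h2": cfg["entry_h2"] if cfg["entry_h2"] > 0 else 0.0,
               "genetic_sd": cfg.get("x1_genetic_sd", 0.3),
               "noise_sd": cfg.get("x1_noise_sd",
                                   0.0 if name == "perfect" else 0.05)}
    tensor = simulate_trajectories(truth, gapped_days(), noise_sd=cfg["noise_sd"],
                                   x1_spec=x1_spec, seed=int(seeds[2]))
    return G, tensor, truth
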