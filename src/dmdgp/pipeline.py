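"""The dynamic genomic-prediction pipeline.

The method in one paragraph: fit a canonical Schur-based DMD per genotype,
treat every entry of the projected-mode matrix Φ and the quasi-triangular
factor R as a quantitative trait, train one RR-BLUP model per entry on the
training genotypes, predict the entries for an unseen genotype from its
markers, reassemble the predicted operator A_P = Φ_P R_P Φ_P†, and forecast
the genotype's multi-trait trajectory either iteratively (one step ahead
from measured states) or recursively (unrolled from a single initial
measurement). Accuracy is the Pearson correlation between predicted and
measured values across the test genotypes, per trait and per timepoint,
averaged over cross-validation folds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .containers import GenotypeMatrix, TraitTensor
from .dmd import (
    PredictedOperator,
    SchurDMDModel,
    build_snapshot_pair,
    fit_schur_dmd,
    forecast_recursive,
    reconstruct_operator,
)
from .markers import (
    GRM,
    GRMEigen,
    KernelEigen,
    RRBLUPFit,
    fit_rrblup,
    grm_eigendecomposition,
    kernel_eigendecomposition,
    predict_rrblup,
    reml_single_component,
)

__all__ = [
    "EntryTraitTable",
    "CVPlan",
    "PredictionResult",
    "DynamicGPBundle",
    "extract_entry_traits",
    "harmonize_orientations",
    "assess_entry_heritability",
    "cross_validate_entry_prediction",
    "select_rank",
    "train_dynamicgp",
    "predict_operator_for_line",
    "run_dynamicgp_cv",
    "evaluate_modes",
    "baseline_rrblup_cv",
    "heritability_consistency_analysis",
    "save_bundle",
    "load_bundle",
]

logger = logging.getLogger("dmdgp")

_MATRIX_ATTRS = {
    "Phi": "Phi", "R": "R", "U": "U_r", "Sigma": "Sigma_r", "V": "V_r",
    "A_tilde": "A_tilde", "Q": "Q",
}
_MATRIX_ORDER = ("Phi", "R", "U", "Sigma", "V", "A_tilde", "Q")


# ---------------------------------------------------------------------------
# cross-validation plans
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Repeated k-fold plan with an optional held-out validation slice.

    Fold assignments are a pure function of (seed, iteration, number of
    lines), so any two runs sharing a plan are evaluated on identical test
    sets (paired comparisons).
    """

    n_iterations: int = 20
    n_folds: int = 5
    seed: int = 0
    validation_fraction: float = 0.0

    def splits(self, n_lines: int):
        """Yield (iteration, fold, train_idx, test_idx, valid_idx)."""
        for it in range(self.n_iterations):
            rng = np.random.default_rng([self.seed, it])
            perm = rng.permutation(n_lines)
            n_valid = int(round(self.validation_fraction * n_lines))
            valid = np.sort(perm[:n_valid])
            rest = perm[n_valid:]
            folds = np.array_split(rest, self.n_folds)
            for fi, test in enumerate(folds):
                train = np.sort(np.concatenate([f for fj, f in enumerate(folds)
                                                if fj != fi]))
                yield it, fi, train, np.sort(test), valid

    def modelled_lines(self, n_lines: int) -> np.ndarray:
        """Line indices taking part in the train/test folds of iteration 0."""
        rng = np.random.default_rng([self.seed, 0])
        perm = rng.permutation(n_lines)
        n_valid = int(round(self.validation_fraction * n_lines))
        return np.sort(perm[n_valid:])


# ---------------------------------------------------------------------------
# entry traits
# ---------------------------------------------------------------------------

@dataclass
class EntryTraitTable:
    """k lines x q matrix-entry traits, labelled (matrix, row, col)."""

    line_ids: list[str]
    entry_labels: list[tuple[str, int, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.line_ids), len(self.entry_labels)):
            raise ValueError("entry table shape does not match ids/labels")
        if len(set(self.entry_labels)) != len(self.entry_labels):
            raise ValueError("entry labels must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("entry values must be finite")


def _model_entries(m: SchurDMDModel, which: tuple[str, ...]) -> tuple[list, np.ndarray]:
    labels, values = [], []
    for name in _MATRIX_ORDER:
        if name not in which:
            continue
        arr = getattr(m, _MATRIX_ATTRS[name])
        if name == "Sigma":
            for i, v in enumerate(arr):
                labels.append((name, i, i))
                values.append(v)
        else:
            for i in range(arr.shape[0]):
                for j in range(arr.shape[1]):
                    labels.append((name, i, j))
                    values.append(arr[i, j])
    return labels, np.asarray(values)


def _sign_flip_U(m: SchurDMDModel, s: np.ndarray) -> None:
    """Apply the orthogonal sign change U <- U S in place (A_r invariant)."""
    m.U_r = m.U_r * s
    m.V_r = m.V_r * s
    m.A_tilde = (m.A_tilde * s).T.copy()
    m.A_tilde = (m.A_tilde * s).T.copy()
    m.Q = m.Q * s


def _sign_flip_Phi(m: SchurDMDModel, d: np.ndarray) -> None:
    """Apply the Schur-basis sign change Phi <- Phi D in place (A_r invariant)."""
    m.Phi = m.Phi * d
    m.R = (m.R * d).T.copy()
    m.R = (m.R * d).T.copy()
    m.Q = (m.Q.T * d).T


def harmonize_orientations(models: dict[str, SchurDMDModel]) -> dict[str, SchurDMDModel]:
    """Align the sign conventions of every model against one reference line.

    A per-model sign convention is necessarily discontinuous somewhere on the
    sphere of mode directions; when a population's shared mode happens to sit
    near that discontinuity, a fraction of lines flips and the flipped factor
    entries stop being comparable across genotypes. Orienting each line's
    U_r and Φ columns by the sign of their inner product with the first
    line's corresponding columns removes this failure mode: in the coherent
    (shared-basis) regime those inner products are bounded away from zero.
    All flips are orthogonal sign changes that leave A_r untouched.
    """
    from copy import deepcopy

    lines = list(models)
    out = {lines[0]: deepcopy(models[lines[0]])}
    ref = out[lines[0]]
    for line in lines[1:]:
        m = deepcopy(models[line])
        s = np.sign(np.einsum("ij,ij->j", ref.U_r, m.U_r))
        s[s == 0] = 1.0
        if (s < 0).any():
            _sign_flip_U(m, s)
        d = np.sign(np.einsum("ij,ij->j", ref.Phi, m.Phi))
        d[d == 0] = 1.0
        if (d < 0).any():
            _sign_flip_Phi(m, d)
        out[line] = m
    return out


def extract_entry_traits(models: dict[str, SchurDMDModel],
                         which: tuple[str, ...] = ("Phi", "R"),
                         harmonize: bool = True) -> EntryTraitTable:
    """One row per line, one column per selected factor entry.

    The default selection {Φ, R} is exactly what the operator reconstruction
    A_P = Φ_P R_P Φ_P† needs; the full selection adds the SVD factors, Ã and
    Q for heritability/predictability screens. Unless ``harmonize=False``,
    sign conventions are aligned across lines first (see
    :func:`harmonize_orientations`).
    """
    unknown = set(which) - set(_MATRIX_ATTRS)
    if unknown:
        raise ValueError(f"unknown matrix name(s) {sorted(unknown)}")
    ranks = {m.r for m in models.values()}
    if len(ranks) != 1:
        raise ValueError(f"models have mixed ranks {sorted(ranks)}")
    if not all(m.canonical for m in models.values()):
        raise ValueError("entry extraction requires canonicalized models")
    if harmonize and len(models) > 1:
        models = harmonize_orientations(models)
    line_ids = list(models)
    labels = None
    rows = []
    for line in line_ids:
        lab, vals = _model_entries(models[line], tuple(which))
        if labels is None:
            labels = lab
        elif lab != labels:
            raise ValueError("inconsistent factor shapes across lines")
        rows.append(vals)
    table = EntryTraitTable(line_ids, labels, np.vstack(rows))
    flat = np.ptp(table.values, axis=0) == 0
    for j in np.flatnonzero(flat):
        logger.warning("entry trait %s is constant across lines", labels[j])
    return table


def assess_entry_heritability(table: EntryTraitTable,
                              K: GRM | GRMEigen) -> dict[tuple, float]:
    """GREML h² per entry column (constant columns -> NaN)."""
    eig = K if isinstance(K, GRMEigen) else grm_eigendecomposition(K)
    out = {}
    for j, label in enumerate(table.entry_labels):
        y = table.values[:, j]
        out[label] = (float("nan") if np.ptp(y) == 0
                      else reml_single_component(y, eig).h2)
    return out


# ---------------------------------------------------------------------------
# accuracy helpers
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, NaN when undefined (fewer than 3 points or constant input)."""
    if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def cross_validate_entry_prediction(table: EntryTraitTable, G: GenotypeMatrix,
                                    plan: CVPlan) -> dict[tuple, float]:
    """Mean RR-BLUP cross-validation accuracy per entry trait.

    Per entry: RR-BLUP trained on the training folds, predicted on the
    held-out fold; accuracy = mean Pearson(true, predicted) over all
    iteration x fold test sets. Constant training columns skip the fold.
    """
    if plan.validation_fraction != 0:
        raise ValueError("entry prediction uses a plain k-fold plan "
                         "(validation_fraction must be 0)")
    if table.line_ids != list(G.line_ids):
        G = G.subset_lines(table.line_ids)
    M = G.dosages.astype(float)
    acc: dict[tuple, list[float]] = {label: [] for label in table.entry_labels}
    for it, fi, train, test, _ in plan.splits(len(table.line_ids)):
        ke = kernel_eigendecomposition(M[train])
        for j, label in enumerate(table.entry_labels):
            y = table.values[:, j]
            if np.ptp(y[train]) == 0:
                logger.warning("entry %s constant in training fold %d/%d; skipped",
                               label, it, fi)
                continue
            fit = fit_rrblup(y[train], ke)
            pred = predict_rrblup(fit, M[test])
            r = _pearson(y[test], pred)
            if np.isfinite(r):
                acc[label].append(r)
    return {label: (float(np.mean(v)) if v else float("nan"))
            for label, v in acc.items()}


# ---------------------------------------------------------------------------
# rank selection
# ---------------------------------------------------------------------------

def _fit_all_lines(t: TraitTensor, r: int) -> dict[str, SchurDMDModel]:
    models = {}
    dropped = []
    for line in t.line_ids:
        try:
            models[line] = fit_schur_dmd(build_snapshot_pair(t, line), r=r)
        except (ValueError, np.linalg.LinAlgError) as exc:
            dropped.append(line)
            logger.warning("line %r dropped from DMD fitting: %s", line, exc)
    if dropped and len(dropped) > 0.2 * t.n_lines:
        raise ValueError(
            f"{len(dropped)} of {t.n_lines} lines have unidentifiable dynamics"
        )
    return models


def select_rank(t: TraitTensor, G: GenotypeMatrix,
                candidates: tuple[int, ...] = (2, 3, 4, 5, 6),
                plan: CVPlan | None = None,
                predictability_floor: float = 0.1) -> tuple[int, dict]:
    """Choose the retained rank r from heritability/predictability screens.

    For each candidate rank the reduced-operator (Ã) entries are screened
    for GREML heritability and RR-BLUP cross-validation predictability on
    the training-testing lines only (any validation slice of the plan is
    excluded). The chosen rank is the largest candidate whose mean Ã-entry
    predictability exceeds ``predictability_floor``; if none qualifies the
    smallest candidate is returned with a no-signal flag.
    """
    if plan is None:
        plan = CVPlan(n_iterations=2, n_folds=5, seed=0)
    if min(candidates) < 2:
        raise ValueError("candidate ranks must be >= 2")
    screen_idx = plan.modelled_lines(t.n_lines)
    lines = [t.line_ids[i] for i in screen_idx]
    t_screen = t.subset_lines(lines)
    G_screen = G.subset_lines(lines)
    screen_plan = CVPlan(plan.n_iterations, plan.n_folds, plan.seed, 0.0)
    from .markers import compute_grm

    eig = grm_eigendecomposition(compute_grm(G_screen))
    report: dict[int, dict] = {}
    feasible = []
    for r in sorted(candidates):
        try:
            models = _fit_all_lines(t_screen, r)
        except ValueError as exc:
            report[r] = {"feasible": False, "reason": str(exc)}
            continue
        table = extract_entry_traits(models, which=("A_tilde",))
        h2 = assess_entry_heritability(table, eig)
        acc = cross_validate_entry_prediction(table, G_screen, screen_plan)
        mean_acc = float(np.nanmean(list(acc.values())))
        report[r] = {
            "feasible": True,
            "mean_heritability": float(np.nanmean(list(h2.values()))),
            "mean_predictability": mean_acc,
            "entry_heritability": {str(k): v for k, v in h2.items()},
            "entry_predictability": {str(k): v for k, v in acc.items()},
        }
        feasible.append(r)
    if not feasible:
        raise ValueError("no candidate rank is feasible for these data")
    passing = [r for r in feasible
               if report[r]["mean_predictability"] > predictability_floor]
    if passing:
        chosen = max(passing)
        report["no_signal"] = False
    else:
        chosen = min(feasible)
        report["no_signal"] = True
        logger.warning("no candidate rank shows marker signal above %.2f; "
                       "falling back to r=%d", predictability_floor, chosen)
    report["chosen"] = chosen
    return chosen, report


# ---------------------------------------------------------------------------
# training and operator prediction
# ---------------------------------------------------------------------------

@dataclass
class DynamicGPBundle:
    """Per-entry RR-BLUP fits for Φ and R plus assembly metadata."""

    r: int
    n_traits: int
    entry_labels: list[tuple[str, int, int]]
    fits: dict[tuple[str, int, int], RRBLUPFit]
    marker_ids: list[str]
    trait_ids: list[str]
    trained_lines: list[str]


def train_dynamicgp(t: TraitTensor, G: GenotypeMatrix, r: int = 2) -> DynamicGPBundle:
    """Fit canonical Schur DMD per line and one RR-BLUP per {Φ, R} entry."""
    common = [l for l in t.line_ids if l in set(G.line_ids)]
    if len(common) < t.n_lines or len(common) < G.n_lines:
        logger.info("intersecting line ids: %d phenotyped, %d genotyped, %d shared",
                    t.n_lines, G.n_lines, len(common))
    if len(common) < 3:
        raise ValueError("need at least 3 lines shared between phenotypes and genotypes")
    t = t.subset_lines(common)
    G = G.subset_lines(common)
    models = _fit_all_lines(t, r)
    table = extract_entry_traits(models, which=("Phi", "R"))
    Gm = G.subset_lines(table.line_ids)
    ke = kernel_eigendecomposition(Gm.dosages.astype(float))
    fits = {}
    for j, label in enumerate(table.entry_labels):
        y = table.values[:, j]
        if np.ptp(y) == 0:
            # structurally constant entry (e.g. the zero subdiagonal of a
            # triangular R): predict the constant, no marker effects
            fits[label] = RRBLUPFit(
                mu=float(y[0]), beta=np.zeros(Gm.n_markers), lam=1.0,
                sigma2_u=0.0, sigma2_e=0.0,
                marker_centering=ke.centering.copy(),
                marker_ids=list(Gm.marker_ids),
            )
            continue
        fits[label] = fit_rrblup(y, ke, marker_ids=list(Gm.marker_ids))
    return DynamicGPBundle(
        r=r, n_traits=t.n_traits, entry_labels=table.entry_labels, fits=fits,
        marker_ids=list(Gm.marker_ids), trait_ids=list(t.trait_ids),
        trained_lines=table.line_ids,
    )


def predict_operator_for_line(bundle: DynamicGPBundle,
                              g_new: np.ndarray) -> PredictedOperator:
    """Assemble Φ_P, R_P from per-entry predictions; A_P = Φ_P R_P Φ_P†."""
    g_new = np.asarray(g_new, dtype=float).ravel()
    if len(g_new) != len(bundle.marker_ids):
        raise ValueError("marker set does not match the trained bundle")
    p, r = bundle.n_traits, bundle.r
    Phi_P = np.zeros((p, r))
    R_P = np.zeros((r, r))
    for label, fit in bundle.fits.items():
        name, i, j = label
        value = float(predict_rrblup(fit, g_new[None, :])[0])
        if name == "Phi":
            Phi_P[i, j] = value
        else:
            R_P[i, j] = value
    A_P = reconstruct_operator(Phi_P, R_P)
    return PredictedOperator(Phi_P=Phi_P, R_P=R_P, A_P=A_P)


# ---------------------------------------------------------------------------
# cross-validated trajectory prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    """Per-trait x per-timepoint accuracy/MSE surfaces from cross-validation."""

    accuracy: np.ndarray
    accuracy_sd: np.ndarray
    mse: np.ndarray
    mode: str
    scenario: str
    trait_ids: list[str]
    time_axis: np.ndarray       # calendar days of the predicted timepoints
    metadata: dict = field(default_factory=dict)
    fold_records: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.nanmean(self.accuracy))

    def trait_mean_accuracy(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.accuracy, axis=1)


def _forecast_line(A: np.ndarray, X: np.ndarray, days: np.ndarray,
                   pred_idx: np.ndarray, start_idx: int, mode: str,
                   gap_policy: str) -> np.ndarray:
    """Forecasts for one line at the timepoint indices ``pred_idx``."""
    if mode == "iterative":
        out = np.empty((X.shape[0], len(pred_idx)))
        for c, j in enumerate(pred_idx):
            gap = int(days[j] - days[j - 1])
            steps = 1 if gap_policy == "unit_step" else gap
            out[:, c] = np.linalg.matrix_power(A, steps) @ X[:, j - 1]
        return out
    if mode == "recursive":
        gaps = np.diff(days[np.r_[start_idx, pred_idx]])
        return forecast_recursive(A, X[:, start_idx], len(pred_idx),
                                  gap_policy=gap_policy, day_gaps=gaps)
    raise ValueError(f"unknown mode {mode!r}")


def evaluate_modes(
    t: TraitTensor,
    G: GenotypeMatrix,
    plan: CVPlan,
    modes: tuple[str, ...] = ("iterative", "recursive"),
    scenario: str = "full_series",
    n_train_timepoints: int | None = None,
    start: str = "first",
    r: int = 2,
    gap_policy: str = "unit_step",
) -> dict[str, PredictionResult]:
    """Cross-validated trajectory prediction, all modes from one training pass.

    ``full_series``: DMD models use all timepoints; predictions cover
    timepoints 2..T. ``holdout_tail``: DMD models (and hence the entry
    models) see only the first ``n_train_timepoints``; forecasts start from
    the first timepoint (``start='first'``) or from the last trained one
    (``start='last_trained'``) and are scored on every later timepoint.
    """
    if t.line_ids != list(G.line_ids):
        common = [l for l in t.line_ids if l in set(G.line_ids)]
        t = t.subset_lines(common)
        G = G.subset_lines(common)
    days = t.time_axis
    T = t.n_timepoints
    if scenario == "full_series":
        t_train = t
        start_idx = 0
        pred_idx = np.arange(1, T)
    elif scenario == "holdout_tail":
        if n_train_timepoints is None or not 1 < n_train_timepoints < T:
            raise ValueError("holdout_tail needs 1 < n_train_timepoints < T")
        t_train = t.subset_timepoints(np.arange(n_train_timepoints))
        if start == "first":
            start_idx = 0
        elif start == "last_trained":
            start_idx = n_train_timepoints - 1
        else:
            raise ValueError(f"unknown start {start!r}")
        pred_idx = np.arange(start_idx + 1, T)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    p = t.n_traits
    n_pred = len(pred_idx)
    M = G.dosages.astype(float)
    per_mode_acc: dict[str, list] = {m: [] for m in modes}
    per_mode_mse: dict[str, list] = {m: [] for m in modes}
    records = []
    for it, fi, train, test, _ in plan.splits(t.n_lines):
        if len(test) < 3:
            logger.warning("iteration %d fold %d: test fold of %d lines; "
                           "correlations undefined", it, fi, len(test))
        train_lines = [t.line_ids[i] for i in train]
        bundle = train_dynamicgp(t_train.subset_lines(train_lines),
                                 G.subset_lines(train_lines), r=r)
        truth = t.values[test][:, :, pred_idx]       # (n_test, p, n_pred)
        preds = {m: np.empty_like(truth) for m in modes}
        for row, li in enumerate(test):
            op = predict_operator_for_line(bundle, M[li])
            X = t.values[li]
            for m in modes:
                preds[m][row] = _forecast_line(op.A_P, X, days, pred_idx,
                                               start_idx, m, gap_policy)
        for m in modes:
            acc = np.full((p, n_pred), np.nan)
            mse = np.full((p, n_pred), np.nan)
            for pi in range(p):
                for ci in range(n_pred):
                    acc[pi, ci] = _pearson(truth[:, pi, ci], preds[m][:, pi, ci])
                    mse[pi, ci] = float(np.mean(
                        (truth[:, pi, ci] - preds[m][:, pi, ci]) ** 2))
            per_mode_acc[m].append(acc)
            per_mode_mse[m].append(mse)
        records.append({"iteration": it, "fold": fi,
                        "test_lines": [t.line_ids[i] for i in test]})

    out = {}
    meta_common = {
        "seed": plan.seed, "n_iterations": plan.n_iterations,
        "n_folds": plan.n_folds, "validation_fraction": plan.validation_fraction,
        "rank": r, "scenario": scenario, "gap_policy": gap_policy,
        "n_train_timepoints": n_train_timepoints, "start": start,
    }
    for m in modes:
        stack_acc = np.stack(per_mode_acc[m])
        stack_mse = np.stack(per_mode_mse[m])
        with np.errstate(invalid="ignore"):
            out[m] = PredictionResult(
                accuracy=np.nanmean(stack_acc, axis=0),
                accuracy_sd=np.nanstd(stack_acc, axis=0),
                mse=np.nanmean(stack_mse, axis=0),
                mode=m, scenario=scenario,
                trait_ids=list(t.trait_ids), time_axis=days[pred_idx],
                metadata={**meta_common, "mode": m},
                fold_records=records,
            )
    return out


def run_dynamicgp_cv(t: TraitTensor, G: GenotypeMatrix, plan: CVPlan,
                     mode: str = "recursive", scenario: str = "full_series",
                     n_train_timepoints: int | None = None,
                     start: str = "first", r: int = 2,
                     gap_policy: str = "unit_step") -> PredictionResult:
    """Single-mode front end for :func:`evaluate_modes`."""
    return evaluate_modes(t, G, plan, modes=(mode,), scenario=scenario,
                          n_train_timepoints=n_train_timepoints, start=start,
                          r=r, gap_policy=gap_policy)[mode]


def baseline_rrblup_cv(t: TraitTensor, G: GenotypeMatrix, plan: CVPlan,
                       train_timepoint: int = 0) -> PredictionResult:
    """Snapshot genomic-prediction baseline.

    Per trait, RR-BLUP is trained on the values at one timepoint; the
    resulting (time-constant) genomic prediction is correlated with the
    measured values at every timepoint from the training one onward.
    """
    if not 0 <= train_timepoint < t.n_timepoints:
        raise ValueError("train_timepoint out of range")
    if t.line_ids != list(G.line_ids):
        common = [l for l in t.line_ids if l in set(G.line_ids)]
        t = t.subset_lines(common)
        G = G.subset_lines(common)
    pred_idx = np.arange(train_timepoint, t.n_timepoints)
    p, n_pred = t.n_traits, len(pred_idx)
    M = G.dosages.astype(float)
    accs, mses = [], []
    for it, fi, train, test, _ in plan.splits(t.n_lines):
        ke = kernel_eigendecomposition(M[train])
        acc = np.full((p, n_pred), np.nan)
        mse = np.full((p, n_pred), np.nan)
        for pi in range(p):
            y = t.values[train, pi, train_timepoint]
            if np.ptp(y) == 0:
                continue
            fit = fit_rrblup(y, ke)
            yhat = predict_rrblup(fit, M[test])
            for ci, ti in enumerate(pred_idx):
                truth = t.values[test, pi, ti]
                acc[pi, ci] = _pearson(truth, yhat)
                mse[pi, ci] = float(np.mean((truth - yhat) ** 2))
        accs.append(acc)
        mses.append(mse)
    stack_acc = np.stack(accs)
    with np.errstate(invalid="ignore"):
        return PredictionResult(
            accuracy=np.nanmean(stack_acc, axis=0),
            accuracy_sd=np.nanstd(stack_acc, axis=0),
            mse=np.nanmean(np.stack(mses), axis=0),
            mode="baseline", scenario="baseline",
            trait_ids=list(t.trait_ids), time_axis=t.time_axis[pred_idx],
            metadata={"seed": plan.seed, "n_iterations": plan.n_iterations,
                      "n_folds": plan.n_folds,
                      "train_timepoint": int(train_timepoint)},
        )


def heritability_consistency_analysis(h2_by_time: np.ndarray,
                                      result: PredictionResult) -> dict:
    """Does temporal stability of heritability explain predictability?

    ``h2_by_time`` is a p x T matrix of per-trait, per-timepoint h². Per
    trait the coefficient of variation CV = sd/mean of h² across time is
    related to the trait's mean prediction accuracy; the Pearson correlation
    across traits and its two-sided t-distribution p-value are reported.
    """
    h2_by_time = np.asarray(h2_by_time, dtype=float)
    if h2_by_time.shape[0] != len(result.trait_ids):
        raise ValueError("h2 matrix rows must match the result's traits")
    mean_h2 = np.nanmean(h2_by_time, axis=1)
    sd_h2 = np.nanstd(h2_by_time, axis=1, ddof=1)
    mean_acc = result.trait_mean_accuracy()
    excluded = [result.trait_ids[i] for i in np.flatnonzero(mean_h2 == 0)]
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean_h2 == 0, np.nan, sd_h2 / mean_h2)
    ok = np.isfinite(cv) & np.isfinite(mean_acc)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 traits with defined CV and accuracy")
    r, pval = stats.pearsonr(cv[ok], mean_acc[ok])
    return {
        "cv_h2": dict(zip(result.trait_ids, cv)),
        "mean_accuracy": dict(zip(result.trait_ids, mean_acc)),
        "correlation": float(r),
        "p_value": float(pval),
        "excluded_traits": excluded,
        "n_traits": int(ok.sum()),
    }


# ---------------------------------------------------------------------------
# bundle serialization
# ---------------------------------------------------------------------------

def save_bundle(bundle: DynamicGPBundle, path: str | Path) -> None:
    payload = {
        "r": bundle.r, "n_traits": bundle.n_traits,
        "marker_ids": bundle.marker_ids, "trait_ids": bundle.trait_ids,
        "trained_lines": bundle.trained_lines,
        "entries": [
            {
                "label": list(label),
                "mu": fit.mu, "lam": fit.lam,
                "sigma2_u": fit.sigma2_u, "sigma2_e": fit.sigma2_e,
                "beta": fit.beta.tolist(),
                "centering": fit.marker_centering.tolist(),
            }
            for label, fit in bundle.fits.items()
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_bundle(path: str | Path) -> DynamicGPBundle:
    with open(path) as fh:
        payload = json.load(fh)
    fits = {}
    labels = []
    for e in payload["entries"]:
        label = (e["label"][0], int(e["label"][1]), int(e["label"][2]))
        labels.append(label)
        fits[label] = RRBLUPFit(
            mu=e["mu"], beta=np.array(e["beta"]), lam=e["lam"],
            sigma2_u=e["sigma2_u"], sigma2_e=e["sigma2_e"],
            marker_centering=np.array(e["centering"]),
            marker_ids=payload["marker_ids"],
        )
    return DynamicGPBundle(
        r=payload["r"], n_traits=payload["n_traits"], entry_labels=labels,
        fits=fits, marker_ids=payload["marker_ids"],
        trait_ids=payload["trait_ids"], trained_lines=payload["trained_lines"],
    )
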