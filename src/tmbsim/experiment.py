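"""The in-silico experiment: repeated splits, psTMB->wesTMB calibration,
the technical-parameter grid, panel-size efficiency thresholds, rule
importance and the VAF x tumor-purity sub-experiment.

A *method* is a (panel, computation rule, detection profile) triple.  For a
cohort with known reference wesTMB it is evaluated by: counting the
rule-surviving mutations inside the panel per sample, perturbing the count
with the detection-error model, dividing by the panel's exonic size
(psTMB), fitting an ordinary-least-squares psTMB -> wesTMB line on the
training split, selecting among the repeated splits on validation R², and
reporting R², RMSLE and discrete accuracy of the estimated wesTMB on the
held-out test split.
"""

from __future__ import annotations

import itertools
import logging
import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .panels import PanelDesign, PanelFamily, mutations_in_panel
from .records import TMB_HIGH, ValidationError
from .tmb import (
    ComputationRule,
    DetectionProfile,
    apparent_count,
    classify_tmb,
    discrete_accuracy,
    filter_frame,
    rgbrp,
    rmsle,
    sample_apparent_count,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "LinearModel",
    "MethodResult",
    "GridSpec",
    "child_seed",
    "split_cohort",
    "calibrate",
    "evaluate_method",
    "run_grid",
    "efficiency_thresholds",
    "saturation_thresholds",
    "rule_importance",
    "vaf_purity_grid",
    "RULE_FLAG_NAMES",
]

RULE_FLAG_NAMES = ("synonymous", "nonsense", "nonstop", "splice_site", "tss", "hotspot_filter")


def child_seed(base_seed: int, purpose: str, index: int = 0) -> int:
    """Stable, platform-independent derived seed (< 2**31)."""
    return zlib.crc32(f"{base_seed}:{purpose}:{index}".encode()) % (2**31)


@dataclass(frozen=True)
class SplitSpec:
    """Repeated train/validation/test splitting, default 8:1:1 x 10."""

    ratios: tuple[float, float, float] = (8.0, 1.0, 1.0)
    repetitions: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValidationError("split ratios must be positive")
        if self.repetitions < 1:
            raise ValidationError("repetitions must be >= 1")

    @property
    def fractions(self) -> tuple[float, float, float]:
        total = sum(self.ratios)
        return tuple(r / total for r in self.ratios)  # type: ignore[return-value]


@dataclass(frozen=True)
class LinearModel:
    """An OLS psTMB -> wesTMB calibration line and its training-set R²."""

    slope: float
    intercept: float
    r_squared: float

    def predict(self, ps: np.ndarray) -> np.ndarray:
        """Estimated wesTMB, floored at zero (TMB cannot be negative)."""
        return np.maximum(0.0, self.slope * np.asarray(ps, dtype=float) + self.intercept)


@dataclass(frozen=True)
class MethodResult:
    """Held-out performance of one (panel, rule, profile) method."""

    panel_name: str
    rule: ComputationRule
    profile: DetectionProfile
    selected_model: LinearModel | None
    selected_repetition: int
    test_r_squared: float
    test_rmsle: float
    test_discrete_accuracy: float
    degenerate: bool = False


def split_cohort(
    sample_ids: Sequence[str], spec: SplitSpec, repetition_index: int
) -> tuple[list[str], list[str], list[str]]:
    """One deterministic 8:1:1 partition of the cohort.

    Disjoint, covering, sizes within 1 of the exact ratios; reproducible
    given (base_seed, repetition_index).
    """
    ids = list(sample_ids)
    n = len(ids)
    if n < 10:
        raise ValidationError(f"need >= 10 samples to split 8:1:1, got {n}")
    rng = np.random.default_rng(child_seed(spec.base_seed, "split", repetition_index))
    order = rng.permutation(n)
    f_train, f_val, _ = spec.fractions
    n_train = int(round(n * f_train))
    n_val = int(round(n * f_val))
    n_train = min(n_train, n - 2)
    n_val = max(1, min(n_val, n - n_train - 1))
    train = [ids[i] for i in order[:n_train]]
    val = [ids[i] for i in order[n_train : n_train + n_val]]
    test = [ids[i] for i in order[n_train + n_val :]]
    return train, val, test


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def _fit_ols(x: np.ndarray, y: np.ndarray) -> LinearModel:
    slope, intercept = np.polyfit(x, y, 1)
    return LinearModel(float(slope), float(intercept), _r2(y, slope * x + intercept))


def calibrate(
    ps: np.ndarray,
    wes: np.ndarray,
    spec: SplitSpec,
    sample_ids: Sequence[str] | None = None,
    tmb_cutoff: float = 10.0,
    allow_constant: bool = False,
) -> tuple[LinearModel | None, int, dict[str, float], bool]:
    """Fit/select/report the psTMB -> wesTMB calibration over repeated splits.

    One OLS line per repetition (fitted on train); the winner is chosen by
    validation R², ties broken by lower validation RMSLE, then lower
    repetition index; metrics are reported on that repetition's test split.

    Returns ``(model, repetition, test_metrics, degenerate)``; degenerate
    means the psTMB had zero variance on train.  By default degenerate
    repetitions are dropped (and the result flagged when none survive);
    with ``allow_constant`` they instead fall back to the constant
    predictor (slope 0, intercept = train-mean wesTMB) — the TMB report a
    lab would still produce when a filter removes every mutation.
    """
    ps = np.asarray(ps, dtype=float)
    wes = np.asarray(wes, dtype=float)
    if ps.shape != wes.shape:
        raise ValidationError("ps and wes must align")
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(len(ps))]
    index = {sid: i for i, sid in enumerate(ids)}

    candidates = []
    for rep in range(spec.repetitions):
        train, val, test = split_cohort(ids, spec, rep)
        tr = np.asarray([index[s] for s in train])
        va = np.asarray([index[s] for s in val])
        te = np.asarray([index[s] for s in test])
        constant = bool(np.ptp(ps[tr]) < 1e-12)
        if constant and not allow_constant:
            continue
        if constant:
            model = LinearModel(0.0, float(wes[tr].mean()), 0.0)
        else:
            model = _fit_ols(ps[tr], wes[tr])
        e_val = model.predict(ps[va])
        candidates.append(
            (
                -_r2(wes[va], e_val),
                rmsle(e_val, wes[va]),
                rep,
                model,
                te,
                constant,
            )
        )
    if not candidates:
        nan = float("nan")
        return None, -1, {"r_squared": nan, "rmsle": nan, "discrete_accuracy": nan}, True
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    _, _, rep, model, te, constant = candidates[0]
    e_test = model.predict(ps[te])
    pred_cls = [classify_tmb(v, tmb_cutoff) for v in e_test]
    ref_cls = [classify_tmb(v, tmb_cutoff) for v in wes[te]]
    metrics = {
        "r_squared": _r2(wes[te], e_test),
        "rmsle": rmsle(e_test, wes[te]),
        "discrete_accuracy": discrete_accuracy(pred_cls, ref_cls),
    }
    return model, rep, metrics, constant


def _ps_tmb_vector(
    samples: pd.DataFrame,
    panel_mutations: pd.DataFrame,
    rule: ComputationRule,
    profile: DetectionProfile,
    panel_size_mb: float,
    count_mode: str = "expected",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """psTMB per sample (aligned to ``samples`` order) for one method."""
    kept = filter_frame(panel_mutations, rule)
    counts = samples["sample_id"].map(kept.groupby("sample_id").size()).fillna(0).to_numpy()
    if count_mode == "expected":
        apparent = np.array([apparent_count(c, profile) for c in counts])
    elif count_mode == "stochastic":
        if rng is None:
            raise ValidationError("stochastic mode needs an rng")
        apparent = np.array(
            [sample_apparent_count(int(c), profile, rng) for c in counts], dtype=float
        )
    else:
        raise ValidationError(f"unknown count_mode {count_mode!r}")
    return apparent / panel_size_mb


def evaluate_method(
    panel: PanelDesign,
    rule: ComputationRule,
    profile: DetectionProfile,
    samples: pd.DataFrame,
    mutations: pd.DataFrame,
    spec: SplitSpec,
    tmb_cutoff: float = 10.0,
    count_mode: str = "expected",
    _panel_mutations: pd.DataFrame | None = None,
) -> MethodResult:
    """Evaluate one synthetic panel-based TMB method on a cohort.

    ``samples`` must carry ``ref_wes_tmb``.  ``_panel_mutations`` lets a
    caller that sweeps many rules over one panel pass the panel intersection
    precomputed.
    """
    pm = _panel_mutations if _panel_mutations is not None else mutations_in_panel(mutations, panel)
    rng = None
    if count_mode == "stochastic":
        purpose = (
            f"apparent:{panel.name}:{sorted(rule.included_classes)}:{rule.filter_hotspots}:"
            f"{rule.vaf_cutoff:.6f}:{profile.recall:.6f}:{profile.precision:.6f}"
        )
        rng = np.random.default_rng(child_seed(spec.base_seed, purpose))
    ps = _ps_tmb_vector(samples, pm, rule, profile, panel.exonic_size_mb, count_mode, rng)
    model, rep, metrics, degenerate = calibrate(
        ps, samples["ref_wes_tmb"].to_numpy(), spec, samples["sample_id"], tmb_cutoff
    )
    return MethodResult(
        panel_name=panel.name,
        rule=rule,
        profile=profile,
        selected_model=model,
        selected_repetition=rep,
        test_r_squared=metrics["r_squared"],
        test_rmsle=metrics["rmsle"],
        test_discrete_accuracy=metrics["discrete_accuracy"],
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class GridSpec:
    """Axes of the technical-parameter grid.

    Defaults cover the five optional inclusion flags, hotspot filtering,
    VAF cutoffs of 1/2/3/5/10% and a 0.1-step recall/precision lattice over
    [0.5, 1.0] restricted to recall >= precision.
    """

    synonymous: tuple[bool, ...] = (False, True)
    nonsense: tuple[bool, ...] = (False, True)
    nonstop: tuple[bool, ...] = (False, True)
    splice_site: tuple[bool, ...] = (False, True)
    tss: tuple[bool, ...] = (False, True)
    hotspot_filter: tuple[bool, ...] = (False, True)
    vaf_cutoffs: tuple[float, ...] = (0.01, 0.02, 0.03, 0.05, 0.10)
    recalls: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    precisions: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)

    def profiles(self) -> list[DetectionProfile]:
        """Recall/precision pairs with recall >= precision."""
        return [
            DetectionProfile(r, p)
            for r in self.recalls
            for p in self.precisions
            if r >= p - 1e-12
        ]

    def combinations(self) -> list[tuple[dict[str, bool], float, DetectionProfile]]:
        flag_axes = [
            self.synonymous,
            self.nonsense,
            self.nonstop,
            self.splice_site,
            self.tss,
            self.hotspot_filter,
        ]
        out = []
        for flags in itertools.product(*flag_axes):
            fdict = dict(zip(RULE_FLAG_NAMES, flags))
            for vaf in self.vaf_cutoffs:
                for prof in self.profiles():
                    out.append((fdict, vaf, prof))
        return out

    def n_combinations(self) -> int:
        return len(self.combinations())


def _combo_key(panel_name: str, flags: Mapping[str, bool], vaf: float, prof: DetectionProfile) -> str:
    raw = f"{panel_name}|{sorted(flags.items())}|{vaf:.6f}|{prof.recall:.6f}|{prof.precision:.6f}"
    return format(zlib.crc32(raw.encode()), "08x")


def run_grid(
    family: PanelFamily | Sequence[PanelDesign],
    grid: GridSpec,
    samples: pd.DataFrame,
    mutations: pd.DataFrame,
    spec: SplitSpec,
    tmb_cutoff: float = 10.0,
    count_mode: str = "expected",
    cache: dict | None = None,
) -> pd.DataFrame:
    """Evaluate every grid combination on every panel.

    Returns a tidy table, one row per (panel x rule x profile).  ``cache``
    (a dict keyed by combination hash) makes re-runs resumable: cached rows
    are reused verbatim.
    """
    panels = list(family)
    combos = grid.combinations()
    rows = []
    for pi, panel in enumerate(panels):
        pm = mutations_in_panel(mutations, panel)
        logger.info(
            "panel %s (%d/%d): %d genes, %.3f Mb, %d combinations",
            panel.name, pi + 1, len(panels), panel.n_genes, panel.exonic_size_mb, len(combos),
        )
        for flags, vaf, prof in combos:
            key = _combo_key(panel.name, flags, vaf, prof)
            if cache is not None and key in cache:
                rows.append(cache[key])
                continue
            rule = ComputationRule.from_flags(vaf_cutoff=vaf, **flags)
            res = evaluate_method(
                panel, rule, prof, samples, mutations, spec,
                tmb_cutoff=tmb_cutoff, count_mode=count_mode, _panel_mutations=pm,
            )
            row = {
                "combo_id": key,
                "panel_name": panel.name,
                "n_genes": panel.n_genes,
                "exonic_size_mb": panel.exonic_size_mb,
                **flags,
                "vaf_cutoff": vaf,
                "recall": prof.recall,
                "precision": prof.precision,
                "rgbrp": rgbrp(prof),
                "slope": res.selected_model.slope if res.selected_model else float("nan"),
                "intercept": res.selected_model.intercept if res.selected_model else float("nan"),
                "selected_repetition": res.selected_repetition,
                "test_r_squared": res.test_r_squared,
                "test_rmsle": res.test_rmsle,
                "test_discrete_accuracy": res.test_discrete_accuracy,
                "degenerate": res.degenerate,
            }
            if cache is not None:
                cache[key] = row
            rows.append(row)
    return pd.DataFrame(rows)


def _smooth(y: np.ndarray) -> np.ndarray:
    """Endpoint-preserving 3-point moving average (keeps monotonicity)."""
    if len(y) < 3:
        return y
    out = y.copy()
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    return out


def saturation_thresholds(
    sizes: np.ndarray, scores: np.ndarray
) -> dict[str, float]:
    """95%-of-plateau and knee thresholds of a saturating score-vs-size curve.

    The raw best-score-per-size points are made monotone with an isotonic
    fit, lightly smoothed, and then: ``size_95`` is the smallest size whose
    fitted score reaches 95% of the plateau (the fitted value at the largest
    size); ``knee_size`` is the interior point with maximum distance between
    the fitted curve and the chord joining its endpoints, both axes
    normalized to [0, 1] first.
    """
    sizes = np.asarray(sizes, dtype=float)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(sizes)
    sizes, scores = sizes[order], scores[order]
    if len(np.unique(sizes)) < len(sizes):
        raise ValidationError("sizes must be distinct (take best score per size first)")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = _smooth(iso.fit_transform(sizes, scores))
    if np.ptp(fitted) < 1e-12:
        # flat curve: any size meets the plateau; knee undefined -> smallest
        return {"size_95": float(sizes[0]), "knee_size": float(sizes[0])}
    plateau = fitted[-1]
    reach = fitted >= 0.95 * plateau
    size_95 = float(sizes[np.argmax(reach)]) if reach.any() else float(sizes[-1])
    x = (sizes - sizes[0]) / (sizes[-1] - sizes[0])
    y = (fitted - fitted[0]) / (fitted[-1] - fitted[0])
    dist = y - x  # signed distance to chord (x rising to 1), scaled by sqrt 2
    interior = slice(1, len(sizes) - 1)
    knee_idx = 1 + int(np.argmax(dist[interior]))
    return {"size_95": size_95, "knee_size": float(sizes[knee_idx])}


def efficiency_thresholds(
    results: pd.DataFrame,
    metric: str = "discrete_accuracy",
    size_column: str = "exonic_size_mb",
) -> dict[str, float]:
    """Panel-size thresholds from a grid-result table.

    Takes the best combination per panel size (max for accuracy-type
    metrics; RMSLE is mapped to the bounded score exp(-RMSLE) so "95% of
    the optimum" is well-posed for a loss) and applies
    :func:`saturation_thresholds`.
    """
    col = f"test_{metric}" if f"test_{metric}" in results.columns else metric
    if col not in results.columns:
        raise ValidationError(f"no metric column {metric!r} in results")
    if "degenerate" in results.columns:
        ok = results[~results["degenerate"].astype(bool)]
    else:
        ok = results
    if metric.endswith("rmsle"):
        score = np.exp(-ok[col])
    else:
        score = ok[col]
    best = score.groupby(ok[size_column]).max()
    if len(best) < 10:
        raise ValidationError(f"need >= 10 distinct panel sizes, got {len(best)}")
    fitted_raw = IsotonicRegression(increasing=True).fit_transform(
        best.index.to_numpy(float), best.to_numpy(float)
    )
    if np.any(np.diff(fitted_raw) < -1e-9):
        warnings.warn("fitted plateau not monotone; thresholds reported anyway")
    return saturation_thresholds(best.index.to_numpy(float), best.to_numpy(float))


def rule_importance(
    results: pd.DataFrame,
    rule_columns: Sequence[str] = RULE_FLAG_NAMES,
    top_quantile: float = 0.95,
) -> pd.DataFrame:
    """Which rules the top-performing combinations agree on, per panel.

    For each panel the *top* combinations are those jointly above the
    ``top_quantile`` of R² and discrete accuracy and below the complementary
    quantile of RMSLE.  Per rule the summary counts panels where at least
    one / 100% / 0% of top combinations include it; ``matters_pct`` is the
    share of panels whose top combinations are unanimous either way.
    """
    summaries = {
        rule: {"at_least_one": 0, "always_in": 0, "always_out": 0, "unanimous": 0}
        for rule in rule_columns
    }
    n_panels_used = 0
    for panel_name, grp in results.groupby("panel_name"):
        grp = grp[~grp["degenerate"].astype(bool)] if "degenerate" in grp else grp
        if len(grp) < 20:
            warnings.warn(
                f"panel {panel_name!r}: only {len(grp)} combinations; percentile unstable"
            )
        top = grp[
            (grp["test_r_squared"] >= grp["test_r_squared"].quantile(top_quantile))
            & (grp["test_discrete_accuracy"] >= grp["test_discrete_accuracy"].quantile(top_quantile))
            & (grp["test_rmsle"] <= grp["test_rmsle"].quantile(1 - top_quantile))
        ]
        if top.empty:
            warnings.warn(f"panel {panel_name!r}: no combination passes all three cuts")
            continue
        n_panels_used += 1
        for rule in rule_columns:
            included = top[rule].astype(bool)
            if included.any():
                summaries[rule]["at_least_one"] += 1
            if included.all():
                summaries[rule]["always_in"] += 1
            if not included.any():
                summaries[rule]["always_out"] += 1
            if included.all() or not included.any():
                summaries[rule]["unanimous"] += 1
    rows = []
    for rule in rule_columns:
        s = summaries[rule]
        rows.append(
            {
                "rule": rule,
                "at_least_one": s["at_least_one"],
                "always_in": s["always_in"],
                "always_out": s["always_out"],
                "matters_pct": 100.0 * s["unanimous"] / n_panels_used if n_panels_used else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def vaf_purity_grid(
    samples: pd.DataFrame,
    mutations: pd.DataFrame,
    panel: PanelDesign,
    spec: SplitSpec,
    target_purities: Sequence[float] = (0.10, 0.20, 0.30, 0.40),
    vaf_cutoffs: Sequence[float] = (0.01, 0.02, 0.03, 0.05, 0.10),
    base_rule: ComputationRule | None = None,
    profile: DetectionProfile = DetectionProfile(1.0, 1.0),
    tmb_cutoff: float = 10.0,
) -> pd.DataFrame:
    """TMB accuracy across VAF cutoffs at simulated (diluted) tumor purity.

    Each mutation's VAF is rescaled by target_purity / original_purity
    (never above the original VAF — dilution only); samples whose original
    purity is below the target are skipped with a warning.  ``target_purity``
    of None/NaN means no rescaling.  For each (purity, cutoff) cell the
    rescaled cohort is refiltered at the cutoff and re-calibrated, and the
    held-out RMSLE / discrete accuracy reported.
    """
    base_rule = base_rule or ComputationRule()
    purity_of = samples.set_index("sample_id")["tumor_purity"]
    rows = []
    for tp in target_purities:
        if tp is None or (isinstance(tp, float) and np.isnan(tp)):
            eligible = samples
            scale = pd.Series(1.0, index=purity_of.index)
        else:
            skipped = samples[samples["tumor_purity"] < tp]
            if len(skipped):
                warnings.warn(
                    f"target purity {tp:.0%}: skipping {len(skipped)} samples with lower "
                    "original purity"
                )
            eligible = samples[samples["tumor_purity"] >= tp]
            scale = np.minimum(1.0, tp / purity_of)
        if len(eligible) < 10:
            warnings.warn(f"target purity {tp}: fewer than 10 eligible samples; cell skipped")
            continue
        muts = mutations[mutations["sample_id"].isin(eligible["sample_id"])].copy()
        muts["vaf"] = muts["vaf"] * muts["sample_id"].map(scale)
        pm = mutations_in_panel(muts, panel)
        for cutoff in vaf_cutoffs:
            rule = replace(base_rule, vaf_cutoff=cutoff)
            ps = _ps_tmb_vector(eligible, pm, rule, profile, panel.exonic_size_mb)
            _, _, metrics, degenerate = calibrate(
                ps, eligible["ref_wes_tmb"].to_numpy(), spec, eligible["sample_id"],
                tmb_cutoff, allow_constant=True,
            )
            rows.append(
                {
                    "target_purity": tp,
                    "vaf_cutoff": cutoff,
                    "n_samples": len(eligible),
                    "test_rmsle": metrics["rmsle"],
                    "test_discrete_accuracy": metrics["discrete_accuracy"],
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)
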