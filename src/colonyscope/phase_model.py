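"""Growth-phase modelling and picking-time prediction.

A tracked colony's growth curve (area vs day) is summarised per day by four
features: the first-order difference of area, the second-order difference,
the area itself, and the number of days since the colony first appeared.
Curve cohorts are screened for abnormal growth (over/undergrowth) by the mean
first-order difference between days 10 and 20; the remaining curves train a
four-state left-to-right hidden Markov model with diagonal-Gaussian emissions
over the (z-scored) features.

Training is partially supervised: expert picking-day annotations clamp two
stage blocks -- from the track start to two days after the first positive
frame the state is the *first* stage, and from one day ahead of the picking
day to the end it is the *mature* stage -- while the unlabelled middle is
free and is initialized by splitting it into two periods of similar length.
Baum-Welch (EM) runs from many random initializations and the best-likelihood
model wins.  Decoding uses Viterbi for the stage path and forward-backward
smoothing for the per-day posterior of the mature state; the picking trigger
fires on the first day this posterior reaches a threshold (default 0.3, the
value calibrated from expert picks; a posterior saturating at 1 flags
overgrowth/differentiation risk).

The model is exposed statsmodels-style: :class:`GrowthPhaseHMM` is built
from data and ``fit()`` returns a :class:`GrowthPhaseResults` carrying the
estimates, diagnostics and a ``summary()`` table.  Thin module-level
functions (``baum_welch``, ``viterbi``, ``mature_posterior``, ...) wrap the
same machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .segment_track import GrowthCurve

FEATURE_NAMES = ("d_area", "dd_area", "area", "growth_days")

# stage codes used in StageLabels
STAGE_UNKNOWN, STAGE_FIRST, STAGE_MATURE = 0, 1, 2

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# features, stage labels, abnormality screening
# ---------------------------------------------------------------------------


@dataclass
class FeatureSequence:
    """Per-day 4-feature vectors of one growth curve."""

    days: np.ndarray
    X: np.ndarray  # (T, 4)
    track_id: int = -1

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.days), len(FEATURE_NAMES)):
            raise ValueError(f"X must be (T, {len(FEATURE_NAMES)})")


@dataclass
class StageLabels:
    """Partial per-day stage annotation of one training curve."""

    days: np.ndarray
    stage: np.ndarray  # STAGE_* codes
    picking_day: int
    first_positive_day: int

    def clamp_mask(self, n_states: int) -> np.ndarray:
        """(T, K) boolean mask of states admissible on each day."""
        mask = np.ones((len(self.days), n_states), dtype=bool)
        mask[self.stage == STAGE_FIRST] = False
        mask[self.stage == STAGE_FIRST, 0] = True
        mask[self.stage == STAGE_MATURE] = False
        mask[self.stage == STAGE_MATURE, n_states - 1] = True
        return mask


def extract_features(
    curve: GrowthCurve,
    first_positive_day: int | None = None,
    relative_rate: bool = False,
) -> FeatureSequence:
    """Build the 4-feature sequence of a curve.

    Undefined boundary differences (f1 on the first day, and hence the
    corresponding term of f2) are set to 0.  With ``relative_rate`` the
    difference features are divided by the previous day's area.
    """
    if len(curve.days) == 0:
        raise ValueError("empty curve")
    fp = int(curve.days[0]) if first_positive_day is None else int(first_positive_day)
    area = curve.areas.astype(float)
    f1 = np.zeros_like(area)
    f1[1:] = np.diff(area)
    if relative_rate:
        f1[1:] = f1[1:] / np.maximum(area[:-1], 1.0)
    f2 = np.zeros_like(area)
    f2[1:] = np.diff(f1)
    f4 = curve.days - fp
    X = np.column_stack([f1, f2, area, f4.astype(float)])
    return FeatureSequence(days=curve.days.copy(), X=X, track_id=curve.track_id)


def make_stage_labels(
    curve: GrowthCurve,
    picking_day: int,
    first_positive_day: int | None = None,
) -> StageLabels:
    """Partial labels: first stage = start..first_positive+2, mature stage =
    picking_day-1..end, everything else unknown."""
    fp = int(curve.days[0]) if first_positive_day is None else int(first_positive_day)
    days = curve.days
    if not (days[0] <= picking_day <= days[-1]):
        raise ValueError(f"picking day {picking_day} outside curve days {days[0]}..{days[-1]}")
    if not (picking_day - 1 > fp + 2):
        raise ValueError(
            f"degenerate colony: mature block (from {picking_day - 1}) overlaps "
            f"first block (to {fp + 2})"
        )
    stage = np.full(len(days), STAGE_UNKNOWN, dtype=np.int8)
    stage[days <= fp + 2] = STAGE_FIRST
    stage[days >= picking_day - 1] = STAGE_MATURE
    return StageLabels(days=days.copy(), stage=stage, picking_day=int(picking_day),
                       first_positive_day=fp)


def first_diff_statistic(
    curve: GrowthCurve, day_lo: int = 10, day_hi: int = 20
) -> float | None:
    """Mean of consecutive-day area differences with both days in
    [day_lo, day_hi]; None if fewer than one such pair exists."""
    day_to_area = dict(zip(curve.days.tolist(), curve.areas.tolist()))
    diffs = [
        day_to_area[d + 1] - day_to_area[d]
        for d in range(day_lo, day_hi)
        if d in day_to_area and (d + 1) in day_to_area
    ]
    return float(np.mean(diffs)) if diffs else None


def filter_abnormal(
    curves: Sequence[GrowthCurve],
    day_lo: int = 10,
    day_hi: int = 20,
    bounds: tuple[float, float] | None = None,
    method: str = "robust",
):
    """Screen a cohort for abnormal (over/undergrown) curves.

    The screening statistic is the mean first-order difference of area over
    days ``[day_lo, day_hi]``.  With ``bounds=None`` the acceptance band is
    estimated from the cohort itself as its 5th..95th percentile range:
    ``method="robust"`` (default) uses the Gaussian-equivalent estimate
    median +/- 1.645 * 1.4826 * MAD, which still estimates the normal
    subpopulation's band when a minority of outliers contaminates the cohort;
    ``method="quantile"`` uses the empirical cohort quantiles.

    Returns ``(normal, rejected)`` where ``rejected`` is a list of
    ``(curve, reason)`` pairs.
    """
    stats = [first_diff_statistic(c, day_lo, day_hi) for c in curves]
    if bounds is None:
        vals = np.array([s for s in stats if s is not None], dtype=float)
        if len(vals) == 0:
            bounds = (-np.inf, np.inf)
        elif method == "robust":
            med = float(np.median(vals))
            mad = float(np.median(np.abs(vals - med)))
            scale = 1.4826 * mad
            bounds = (med - 1.645 * scale, med + 1.645 * scale)
        elif method == "quantile":
            bounds = tuple(np.quantile(vals, [0.05, 0.95]))
        else:
            raise ValueError(f"unknown bounds method {method!r}")
    lo, hi = bounds
    normal, rejected = [], []
    for curve, s in zip(curves, stats):
        if s is None:
            rejected.append((curve, "insufficient window coverage"))
        elif s < lo:
            rejected.append((curve, f"mean growth rate {s:.1f} below bound {lo:.1f}"))
        elif s > hi:
            rejected.append((curve, f"mean growth rate {s:.1f} above bound {hi:.1f}"))
        else:
            normal.append(curve)
    return normal, rejected


# ---------------------------------------------------------------------------
# HMM numerics (scaled forward-backward, Viterbi, EM)
# ---------------------------------------------------------------------------


def _log_emissions(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(T, K) log diagonal-Gaussian densities."""
    diff = X[:, None, :] - means[None, :, :]  # (T, K, F)
    return -0.5 * np.sum(
        _LOG2PI + np.log(variances)[None] + diff**2 / variances[None], axis=2
    )


def _forward_backward(pi, A, logB, mask=None):
    """Scaled forward-backward with optional per-day state clamping.

    Returns (loglik, gamma, xi_sum) or (None, None, None) if the sequence has
    zero probability under the parameters (degenerate clamping/topology).
    ``xi_sum`` is the (K, K) sum over t of transition posteriors.
    """
    T, K = logB.shape
    logb = logB.copy()
    if mask is not None:
        logb[~mask] = -np.inf
    offsets = np.max(logb, axis=1)
    if not np.isfinite(offsets).all():
        return None, None, None
    b = np.exp(logb - offsets[:, None])  # (T, K), max 1 per row

    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * b[0]
    c[0] = a.sum()
    if c[0] <= 0:
        return None, None, None
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * b[t]
        c[t] = a.sum()
        if c[t] <= 0:
            return None, None, None
        alpha[t] = a / c[t]
    loglik = float(np.log(c).sum() + offsets.sum())

    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        nxt = b[t + 1] * beta[t + 1]
        beta[t] = (A @ nxt) / c[t + 1]
        xi_sum += (alpha[t][:, None] * A * nxt[None, :]) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return loglik, gamma, xi_sum


def _viterbi_path(pi, A, logB, mask=None):
    """MAP state path (0-based); ties break toward the lower state index."""
    T, K = logB.shape
    logb = logB.copy()
    if mask is not None:
        logb[~mask] = -np.inf
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
        logA = np.log(A)
    delta = logpi + logb[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA  # (K_prev, K)
        back[t] = scores.argmax(axis=0)  # first max -> lower prev state
        delta = scores[back[t], np.arange(K)] + logb[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _allowed_transitions(K: int, topology: str) -> np.ndarray:
    if topology == "left_to_right":
        return np.triu(np.ones((K, K), dtype=bool))
    if topology == "full":
        return np.ones((K, K), dtype=bool)
    raise ValueError(f"unknown topology {topology!r}")


def _segment_assignment(T: int, K: int, stage: np.ndarray | None) -> np.ndarray:
    """Initial per-day state assignment: clamp labelled blocks, split the
    unlabelled middle into equal-length periods over the free states."""
    assign = np.empty(T, dtype=int)
    if stage is None:
        edges = np.linspace(0, T, K + 1)
        for k in range(K):
            assign[int(edges[k]) : int(edges[k + 1])] = k
        return assign
    assign[stage == STAGE_FIRST] = 0
    assign[stage == STAGE_MATURE] = K - 1
    free = np.flatnonzero(stage == STAGE_UNKNOWN)
    if len(free):
        n_mid = max(K - 2, 1)
        edges = np.linspace(0, len(free), n_mid + 1)
        for k in range(n_mid):
            assign[free[int(edges[k]) : int(edges[k + 1])]] = min(1 + k, K - 1)
    return assign


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class GrowthPhaseHMM:
    """Left-to-right Gaussian-emission HMM over growth-curve features.

    Parameters
    ----------
    sequences
        Training :class:`FeatureSequence` objects.
    labels
        Optional parallel :class:`StageLabels`; labelled days clamp their
        state (first stage -> state 1, mature stage -> last state) during EM.
    n_states
        Number of hidden growth phases (default 4).
    topology
        ``"left_to_right"`` (default; states never regress) or ``"full"``.
    """

    def __init__(
        self,
        sequences: Sequence[FeatureSequence],
        labels: Sequence[StageLabels] | None = None,
        n_states: int = 4,
        topology: str = "left_to_right",
    ):
        if not sequences:
            raise ValueError("at least one sequence required")
        if labels is not None and len(labels) != len(sequences):
            raise ValueError("labels must parallel sequences")
        self.sequences = list(sequences)
        self.labels = list(labels) if labels is not None else None
        self.n_states = int(n_states)
        self.topology = topology
        self._allowed = _allowed_transitions(self.n_states, topology)

        allX = np.vstack([s.X for s in sequences])
        self.feature_mean = allX.mean(axis=0)
        self.feature_scale = allX.std(axis=0)
        self.feature_scale[self.feature_scale == 0] = 1.0

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_curves(
        cls,
        curves: Sequence[GrowthCurve],
        picking_days: dict[int, int] | None = None,
        first_positive_days: dict[int, int] | None = None,
        **kwargs,
    ) -> "GrowthPhaseHMM":
        """Build the model straight from growth curves.

        ``picking_days``/``first_positive_days`` map track_id -> day; tracks
        with a picking annotation get clamped stage labels.
        """
        seqs, labels = [], []
        any_labels = False
        for c in curves:
            fp = None
            if first_positive_days and c.track_id in first_positive_days:
                fp = first_positive_days[c.track_id]
            seqs.append(extract_features(c, first_positive_day=fp))
            if picking_days and c.track_id in picking_days:
                labels.append(make_stage_labels(c, picking_days[c.track_id], fp))
                any_labels = True
            else:
                labels.append(
                    StageLabels(
                        days=c.days.copy(),
                        stage=np.full(len(c.days), STAGE_UNKNOWN, dtype=np.int8),
                        picking_day=-1,
                        first_positive_day=int(c.days[0]) if len(c.days) else -1,
                    )
                )
        return cls(seqs, labels if any_labels else None, **kwargs)

    @classmethod
    def from_dataframe(cls, df, picking_days=None, **kwargs) -> "GrowthPhaseHMM":
        """From a tidy table with columns track_id, day, area_px."""
        curves = []
        for tid, grp in df.sort_values("day").groupby("track_id"):
            curves.append(
                GrowthCurve(
                    track_id=int(tid),
                    days=grp["day"].to_numpy(),
                    areas=grp["area_px"].to_numpy(),
                )
            )
        return cls.from_curves(curves, picking_days=picking_days, **kwargs)

    # -- internals --------------------------------------------------------
    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean) / self.feature_scale

    def _clamp_masks(self):
        if self.labels is None:
            return [None] * len(self.sequences)
        return [lab.clamp_mask(self.n_states) for lab in self.labels]

    def _init_restart(self, rng: np.random.Generator):
        K = self.n_states
        Xs = [self._standardize(s.X) for s in self.sequences]
        F = Xs[0].shape[1]
        per_state = [[] for _ in range(K)]
        for i, X in enumerate(Xs):
            stage = self.labels[i].stage if self.labels is not None else None
            assign = _segment_assignment(len(X), K, stage)
            for k in range(K):
                if (assign == k).any():
                    per_state[k].append(X[assign == k])
        means = np.zeros((K, F))
        variances = np.ones((K, F))
        for k in range(K):
            if per_state[k]:
                obs = np.vstack(per_state[k])
                means[k] = obs.mean(axis=0)
                variances[k] = np.maximum(obs.var(axis=0), 0.1)
        means = means + rng.normal(0.0, 0.3, size=means.shape)
        variances = variances * np.exp(rng.normal(0.0, 0.3, size=variances.shape))

        A = np.zeros((K, K))
        for i in range(K):
            allowed = np.flatnonzero(self._allowed[i])
            base = np.full(len(allowed), 0.1 / max(len(allowed) - 1, 1))
            base[allowed == i] = 0.6
            if (allowed == i + 1).any():
                base[allowed == i + 1] = 0.3
            A[i, allowed] = rng.dirichlet(20 * base / base.sum() + 0.2)
        base_pi = np.full(K, 0.1 / max(K - 1, 1))
        base_pi[0] = 0.9
        pi = rng.dirichlet(20 * base_pi + 0.1)
        return pi, A, means, variances

    def _em(self, pi, A, means, variances, masks, Xs, max_iter, tol, var_floor):
        history = []
        prev_ll = -np.inf
        K = self.n_states
        F = Xs[0].shape[1]
        for _ in range(max_iter):
            total_ll = 0.0
            pi_acc = np.zeros(K)
            xi_acc = np.zeros((K, K))
            gamma_acc = np.zeros(K)
            mu_acc = np.zeros((K, F))
            sq_acc = np.zeros((K, F))
            gammas = []
            for X, mask in zip(Xs, masks):
                logB = _log_emissions(X, means, variances)
                ll, gamma, xi = _forward_backward(pi, A, logB, mask)
                if ll is None:
                    return None, None, history
                total_ll += ll
                gammas.append(gamma)
                pi_acc += gamma[0]
                xi_acc += xi
                gamma_acc += gamma.sum(axis=0)
                mu_acc += gamma.T @ X
            history.append(total_ll)
            if np.isfinite(prev_ll) and total_ll - prev_ll < tol:
                break  # converged: keep the params that produced total_ll
            prev_ll = total_ll

            # M-step
            pi = pi_acc / pi_acc.sum()
            A_new = np.where(self._allowed, xi_acc, 0.0)
            A_new[self._allowed] = np.maximum(A_new[self._allowed], 1e-12)
            # rows with no outgoing mass (e.g. absorbing final state never
            # left) keep a self-transition
            row_sums = A_new.sum(axis=1)
            A = A_new / row_sums[:, None]
            means = mu_acc / np.maximum(gamma_acc[:, None], 1e-300)
            for X, gamma in zip(Xs, gammas):
                diff = X[:, None, :] - means[None, :, :]
                sq_acc += np.einsum("tk,tkf->kf", gamma, diff**2)
            variances = np.maximum(
                sq_acc / np.maximum(gamma_acc[:, None], 1e-300), var_floor
            )
        return (pi, A, means, variances), history[-1], history

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        n_restarts: int = 2000,
        seed: int = 0,
        max_iter: int = 500,
        tol: float = 1e-6,
        var_floor: float = 1e-6,
    ) -> "GrowthPhaseResults":
        """Multi-restart Baum-Welch; returns the best-likelihood results.

        Restart initializations are seeded deterministically from ``seed``.
        """
        rng = np.random.default_rng(seed)
        restart_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
        Xs = [self._standardize(s.X) for s in self.sequences]
        masks = self._clamp_masks()

        best = None
        for rs in restart_seeds:
            pi, A, means, variances = self._init_restart(np.random.default_rng(rs))
            params, ll, history = self._em(
                pi, A, means, variances, masks, Xs, max_iter, tol, var_floor
            )
            if params is None:
                continue
            if best is None or ll > best[0]:
                best = (ll, params, history)
        if best is None:
            raise RuntimeError("all Baum-Welch restarts degenerate")
        ll, (pi, A, means, variances), history = best
        return GrowthPhaseResults(
            model=self,
            pi=pi,
            A=A,
            means=means,
            variances=variances,
            loglik=ll,
            loglik_history=np.asarray(history),
            n_restarts=n_restarts,
            seed=seed,
        )


@dataclass
class GrowthPhaseResults:
    """Fitted growth-phase HMM: parameters, diagnostics, decoders.

    Emission parameters are stored on the standardized feature scale; the
    standardization transform lives on the model and ``state_means()``
    reports means in original units.  States are reported 1-based (state 1 =
    first stage, state ``K`` = mature stage).
    """

    model: GrowthPhaseHMM
    pi: np.ndarray
    A: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    loglik_history: np.ndarray
    n_restarts: int
    seed: int
    picking_threshold: float = 0.3

    @property
    def n_states(self) -> int:
        return self.model.n_states

    # -- decoding ---------------------------------------------------------
    def _prepared(self, seq: FeatureSequence):
        X = self.model._standardize(seq.X)
        return _log_emissions(X, self.means, self.variances)

    def predict_states(self, seq: FeatureSequence) -> np.ndarray:
        """Viterbi stage path, 1-based."""
        return _viterbi_path(self.pi, self.A, self._prepared(seq)) + 1

    def state_posteriors(self, seq: FeatureSequence) -> np.ndarray:
        """(T, K) smoothed per-day state posteriors (forward-backward)."""
        ll, gamma, _ = _forward_backward(self.pi, self.A, self._prepared(seq))
        if ll is None:
            raise RuntimeError("sequence has zero likelihood under the model")
        return gamma

    def loglikelihood(self, seq: FeatureSequence) -> float:
        ll, _, _ = _forward_backward(self.pi, self.A, self._prepared(seq))
        if ll is None:
            return -np.inf
        return ll

    def mature_posterior(self, seq: FeatureSequence) -> np.ndarray:
        """Per-day probability of the mature (last) state."""
        return self.state_posteriors(seq)[:, -1]

    def picking_decision(
        self,
        seq: FeatureSequence,
        threshold: float | None = None,
        rule: str = "first_crossing",
    ) -> "PickingDecision":
        scores = self.mature_posterior(seq)
        thr = self.picking_threshold if threshold is None else threshold
        return picking_decision(seq.days, scores, threshold=thr, rule=rule,
                                track_id=seq.track_id)

    # -- reporting --------------------------------------------------------
    def state_means(self) -> np.ndarray:
        """Emission means per state in original feature units."""
        return self.means * self.model.feature_scale + self.model.feature_mean

    def state_stds(self) -> np.ndarray:
        return np.sqrt(self.variances) * self.model.feature_scale

    def summary(self) -> str:
        K = self.n_states
        lines = [
            "Growth-phase HMM results",
            "=" * 64,
            f"states: {K} ({self.model.topology})   sequences: {len(self.model.sequences)}",
            f"restarts: {self.n_restarts}   seed: {self.seed}",
            f"log-likelihood: {self.loglik:.4f}   EM iterations: {len(self.loglik_history)}",
            "",
            "Emission means (original units)",
            "state  " + "  ".join(f"{n:>12s}" for n in FEATURE_NAMES),
        ]
        om, os_ = self.state_means(), self.state_stds()
        for k in range(K):
            lines.append(
                f"{k + 1:>5d}  " + "  ".join(f"{om[k, f]:12.2f}" for f in range(om.shape[1]))
            )
        lines += ["", "Emission standard deviations (original units)"]
        for k in range(K):
            lines.append(
                f"{k + 1:>5d}  " + "  ".join(f"{os_[k, f]:12.2f}" for f in range(os_.shape[1]))
            )
        lines += ["", "Transition matrix"]
        for k in range(K):
            lines.append("  ".join(f"{self.A[k, j]:7.4f}" for j in range(K)))
        lines += ["", "Initial distribution", "  ".join(f"{p:7.4f}" for p in self.pi)]
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "format": "colonyscope-phase-hmm",
            "version": 1,
            "n_states": self.n_states,
            "topology": self.model.topology,
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "feature_mean": self.model.feature_mean.tolist(),
            "feature_scale": self.model.feature_scale.tolist(),
            "loglik": self.loglik,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "picking_threshold": self.picking_threshold,
            "feature_names": list(FEATURE_NAMES),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "GrowthPhaseResults":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "colonyscope-phase-hmm":
            raise ValueError(f"not a phase-HMM file: {path}")
        K = payload["n_states"]
        # reconstruct a shell model carrying the standardization transform
        dummy_seq = FeatureSequence(
            days=np.arange(2), X=np.zeros((2, len(FEATURE_NAMES)))
        )
        model = GrowthPhaseHMM([dummy_seq], n_states=K, topology=payload["topology"])
        model.sequences = []
        model.feature_mean = np.asarray(payload["feature_mean"])
        model.feature_scale = np.asarray(payload["feature_scale"])
        return cls(
            model=model,
            pi=np.asarray(payload["pi"]),
            A=np.asarray(payload["A"]),
            means=np.asarray(payload["means"]),
            variances=np.asarray(payload["variances"]),
            loglik=payload["loglik"],
            loglik_history=np.asarray([]),
            n_restarts=payload["n_restarts"],
            seed=payload["seed"],
            picking_threshold=payload["picking_threshold"],
        )


# ---------------------------------------------------------------------------
# picking decisions
# ---------------------------------------------------------------------------


@dataclass
class PickingDecision:
    """Per-colony trigger day from the mature-phase posterior."""

    track_id: int
    trigger_day: int | None
    days: np.ndarray
    scores: np.ndarray
    threshold: float
    overgrowth_risk: bool = False
    rule: str = "first_crossing"


def picking_decision(
    days: np.ndarray,
    scores: np.ndarray,
    threshold: float = 0.3,
    rule: str = "first_crossing",
    track_id: int = -1,
    overgrowth_level: float = 0.999,
) -> PickingDecision:
    """Trigger day from a mature-posterior series.

    ``rule="first_crossing"`` (default): first day the score reaches the
    threshold.  ``rule="closest"``: the day whose score is closest to the
    threshold (earlier day on ties).  A score saturating at ~1 flags
    overgrowth/differentiation risk.
    """
    days = np.asarray(days)
    scores = np.asarray(scores, dtype=float)
    if len(days) == 0:
        raise ValueError("empty score series")
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    trigger: int | None = None
    if rule == "first_crossing":
        hits = np.flatnonzero(scores >= threshold)
        if len(hits):
            trigger = int(days[hits[0]])
    elif rule == "closest":
        trigger = int(days[int(np.abs(scores - threshold).argmin())])
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return PickingDecision(
        track_id=track_id,
        trigger_day=trigger,
        days=days,
        scores=scores,
        threshold=threshold,
        overgrowth_risk=bool(scores.max() >= overgrowth_level),
        rule=rule,
    )


def calibrate_threshold(
    series: Sequence[tuple[np.ndarray, np.ndarray, int]],
    grid: np.ndarray | None = None,
    rule: str = "first_crossing",
) -> float:
    """Threshold minimizing mean |trigger_day - expert_day|.

    ``series`` holds (days, scores, expert_day) per track (>= 5 required).
    Candidates default to 0.01..0.99 in steps of 0.01; a missing trigger
    under a candidate costs the track's full day span; ties go to the
    smaller threshold.
    """
    series = list(series)
    if len(series) < 5:
        raise ValueError("calibration requires >= 5 labelled tracks")
    if grid is None:
        grid = np.round(np.arange(0.01, 1.0, 0.01), 2)
    best_thr, best_cost = None, np.inf
    for thr in grid:
        costs = []
        for days, scores, expert in series:
            d = picking_decision(days, scores, threshold=float(thr), rule=rule)
            if d.trigger_day is None:
                costs.append(float(np.max(days) - np.min(days) + 1))
            else:
                costs.append(abs(d.trigger_day - expert))
        cost = float(np.mean(costs))
        if cost < best_cost:
            best_cost, best_thr = cost, float(thr)
    return best_thr


# ---------------------------------------------------------------------------
# functional wrappers (operation-level API)
# ---------------------------------------------------------------------------


def baum_welch(
    sequences: Sequence[FeatureSequence],
    labels: Sequence[StageLabels] | None = None,
    n_states: int = 4,
    n_restarts: int = 2000,
    rng_seed: int = 0,
    **fit_kwargs,
) -> GrowthPhaseResults:
    """Train the phase HMM (multi-restart EM); see :class:`GrowthPhaseHMM`."""
    model = GrowthPhaseHMM(sequences, labels=labels, n_states=n_states)
    return model.fit(n_restarts=n_restarts, seed=rng_seed, **fit_kwargs)


def viterbi(results: GrowthPhaseResults, seq: FeatureSequence) -> np.ndarray:
    """1-based MAP stage path of a sequence under a fitted model."""
    return results.predict_states(seq)


def mature_posterior(results: GrowthPhaseResults, seq: FeatureSequence) -> np.ndarray:
    """Per-day smoothed probability of the mature state."""
    return results.mature_posterior(seq)
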