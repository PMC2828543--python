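"""First-level (within-subject) GLM for SAT fMRI runs.

Each SAT block is modelled as one run.  The design holds six task
conditions — the four cue types (duration 2 s) and the reward outcome
(duration 1.5 s) with its parametric modulation by reinforcement magnitude
(0-100 pence, mean-centred) — each convolved with a canonical double-gamma
haemodynamic response function plus its temporal and dispersion
derivatives, giving 18 task columns, followed by discrete-cosine drift
regressors up to 1/128 Hz and an intercept.  Voxelwise fitting uses
two-pass AR(1) prewhitening: OLS, a pooled bias-corrected lag-1
autocorrelation estimate, whitening of both sides, refit.

Three contrasts are formed on the canonical-HRF columns: parametric
reward outcome, adaptive reward prediction (high- minus low-probability
relevant features), and aberrant reward prediction (subjective-high minus
subjective-low irrelevant features, with the assignment re-derived per
block from the subject's own ratings).

The public surface follows the Model/Results convention:
``FirstLevelModel(designs, data).fit()`` returns a ``FirstLevelResults``
carrying betas, AR(1) estimates and contrast machinery; ``fit_glm`` and
``apply_contrast`` are thin functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import gamma as gamma_dist

from .task import CUE_TYPES, FEEDBACK_DELAY_S, TaskVersion
from .agents import SubjectLog

__all__ = [
    "TR_DEFAULT",
    "CUE_DURATION_S",
    "OUTCOME_DURATION_S",
    "HIGHPASS_CUTOFF_S",
    "PREMATURE_EXCLUSION_S",
    "HRFBasis",
    "EventSet",
    "DesignMatrix",
    "ContrastSpec",
    "ContrastResult",
    "FirstLevelModel",
    "FirstLevelResults",
    "hrf_basis",
    "screen_events",
    "build_design",
    "fit_glm",
    "apply_contrast",
    "contrast_weights",
    "simulate_bold",
]

TR_DEFAULT = 2.73
CUE_DURATION_S = 2.0
OUTCOME_DURATION_S = 1.5
HIGHPASS_CUTOFF_S = 128.0
PREMATURE_EXCLUSION_S = 1.25  # cue excluded if response < 1.25 s after cue onset
MICROTIME = 16                # convolution bins per TR
HRF_LENGTH_S = 32.0

TASK_CONDITIONS = CUE_TYPES + ("outcome", "outcome_x_magnitude")
BASIS_NAMES = ("hrf", "tderiv", "dderiv")


# ---------------------------------------------------------------------------
# HRF basis

@dataclass(eq=False)
class HRFBasis:
    time: np.ndarray
    canonical: np.ndarray
    temporal_derivative: np.ndarray
    dispersion_derivative: np.ndarray
    resolution_s: float

    @property
    def kernels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.canonical, self.temporal_derivative, self.dispersion_derivative)


def _double_gamma(t: np.ndarray, onset_shift: float = 0.0, dispersion: float = 1.0) -> np.ndarray:
    """Canonical double-gamma: response peak 6, undershoot 16, ratio 6."""
    ts = t - onset_shift
    h = gamma_dist.pdf(ts, 6.0, scale=dispersion) - gamma_dist.pdf(ts, 16.0) / 6.0
    return np.where(ts >= 0, h, 0.0)


def hrf_basis(resolution_s: float, duration_s: float = HRF_LENGTH_S) -> HRFBasis:
    """Canonical HRF with temporal and dispersion derivatives.

    The temporal derivative is the finite difference with respect to a 1 s
    onset shift, the dispersion derivative the finite difference with
    respect to the peak dispersion parameter (step 0.01).  All three are
    scaled by the same factor, chosen so the canonical kernel peaks at 1.
    """
    if resolution_s <= 0:
        raise ValueError("resolution_s must be positive")
    t = np.arange(0.0, duration_s, resolution_s)
    h = _double_gamma(t)
    td = (h - _double_gamma(t, onset_shift=1.0)) / 1.0
    dd = (h - _double_gamma(t, dispersion=1.01)) / 0.01
    scale = h.max()
    return HRFBasis(t, h / scale, td / scale, dd / scale, resolution_s)


# ---------------------------------------------------------------------------
# Events

@dataclass(eq=False)
class EventSet:
    """Screened events for one run: cue events plus all outcome events."""

    cues: pd.DataFrame        # onset, duration, condition (cue type)
    outcomes: pd.DataFrame    # onset, duration, magnitude (pence)
    block: int = 1
    n_excluded_cues: int = 0


def screen_events(log: SubjectLog) -> list[EventSet]:
    """Apply the cue-exclusion rules and emit one EventSet per block.

    Cue events are dropped when the subject made no response or responded
    less than 1.25 s after cue onset (extremely premature); all outcome
    events are retained with magnitude equal to the trial payout, since
    the feedback (and its reward-scaled tone) is delivered regardless.
    """
    out = []
    for b in range(1, log.schedule.n_blocks + 1):
        ev = log.events_frame(b)
        resp = ev["response_time"]
        keep = resp.notna() & (resp >= PREMATURE_EXCLUSION_S)
        cues = pd.DataFrame(
            {
                "onset": ev.loc[keep, "onset"],
                "duration": CUE_DURATION_S,
                "condition": ev.loc[keep, "trial_type"],
            }
        ).reset_index(drop=True)
        outcomes = pd.DataFrame(
            {
                "onset": ev["onset"] + ev["probe_delay"] + FEEDBACK_DELAY_S,
                "duration": OUTCOME_DURATION_S,
                "magnitude": ev["payout"].astype(float),
            }
        ).reset_index(drop=True)
        out.append(
            EventSet(cues=cues, outcomes=outcomes, block=b,
                     n_excluded_cues=int((~keep).sum()))
        )
    return out


# ---------------------------------------------------------------------------
# Design matrix

@dataclass(eq=False)
class DesignMatrix:
    frame: pd.DataFrame = field(repr=False)  # scans x columns, index = scan times
    tr: float = TR_DEFAULT
    task_columns: tuple = ()
    drift_columns: tuple = ()
    empty_conditions: tuple = ()
    events: Optional[EventSet] = field(default=None, repr=False)

    @property
    def n_scans(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def plot(self, ax=None):
        """Heat-map view of the (column-normalised) design matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 8))
        x = self.frame.to_numpy().copy()
        norms = np.abs(x).max(axis=0)
        norms[norms == 0] = 1.0
        ax.imshow(x / norms, aspect="auto", cmap="gray", interpolation="nearest")
        ax.set_xticks(range(len(self.columns)))
        ax.set_xticklabels(self.columns, rotation=90, fontsize=6)
        ax.set_ylabel("scan")
        return ax


def _dct_drift(n_scans: int, tr: float, cutoff_s: float = HIGHPASS_CUTOFF_S) -> np.ndarray:
    """Discrete-cosine drift set spanning frequencies below 1/cutoff Hz."""
    k = int(np.floor(2.0 * n_scans * tr / cutoff_s))
    i = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * j * (2 * i + 1) / (2.0 * n_scans))
        for j in range(1, k + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def build_design(
    events: EventSet,
    n_scans: int,
    tr: float = TR_DEFAULT,
) -> DesignMatrix:
    """Convolve the screened events into a run design matrix.

    Each condition's boxcar (magnitude-weighted for the parametric
    modulator, whose magnitudes are mean-centred over all outcome events
    first) is built at a microtime resolution of ``tr/16``, convolved with
    the three-basis HRF set, and sampled at scan onsets.  Drift columns
    span the discrete cosine set up to 1/128 Hz; the intercept comes last.
    """
    run_end = n_scans * tr
    for df, what in ((events.cues, "cue"), (events.outcomes, "outcome")):
        if len(df) and df["onset"].max() >= run_end:
            raise ValueError(f"{what} event at {df['onset'].max():.2f} s is beyond "
                             f"the run end ({run_end:.2f} s)")
        if len(df) and df["onset"].min() < 0:
            raise ValueError(f"negative {what} onset")

    dt = tr / MICROTIME
    basis = hrf_basis(dt)
    pad = len(basis.canonical)
    n_micro = n_scans * MICROTIME + pad

    mags = events.outcomes["magnitude"].to_numpy(dtype=float)
    centered = mags - mags.mean() if len(mags) else mags

    def boxcar(onsets, durations, amplitudes) -> np.ndarray:
        u = np.zeros(n_micro)
        for onset, dur, amp in zip(onsets, durations, amplitudes):
            i0 = int(np.round(onset / dt))
            i1 = max(i0 + 1, int(np.round((onset + dur) / dt)))
            u[i0:i1] += amp
        return u

    data, names, empty = {}, [], []
    sample_idx = np.arange(n_scans) * MICROTIME
    for cond in TASK_CONDITIONS:
        if cond == "outcome":
            df = events.outcomes
            u = boxcar(df["onset"], df["duration"], np.ones(len(df)))
        elif cond == "outcome_x_magnitude":
            df = events.outcomes
            u = boxcar(df["onset"], df["duration"], centered)
        else:
            df = events.cues[events.cues["condition"] == cond]
            u = boxcar(df["onset"], df["duration"], np.ones(len(df)))
        if len(df) == 0:
            empty.append(cond)
        for bname, kernel in zip(BASIS_NAMES, basis.kernels):
            col = np.convolve(u, kernel)[:n_micro][: n_scans * MICROTIME]
            col = col[sample_idx] * dt  # integral convention: dt-invariant scale
            name = f"{cond}:{bname}"
            data[name] = col
            names.append(name)

    drift = _dct_drift(n_scans, tr)
    drift_names = [f"drift_{j + 1:02d}" for j in range(drift.shape[1])]
    for j, name in enumerate(drift_names):
        data[name] = drift[:, j]
    data["intercept"] = np.ones(n_scans)

    frame = pd.DataFrame(data, index=np.arange(n_scans) * tr)
    return DesignMatrix(
        frame=frame,
        tr=tr,
        task_columns=tuple(names),
        drift_columns=tuple(drift_names),
        empty_conditions=tuple(empty),
        events=events,
    )


# ---------------------------------------------------------------------------
# Contrasts

@dataclass
class ContrastSpec:
    name: str  # parametric_outcome | adaptive | aberrant
    weights: Optional[pd.Series] = None  # explicit weights override


CONTRAST_NAMES = ("parametric_outcome", "adaptive", "aberrant")


def contrast_weights(
    columns: Sequence[str],
    name: str,
    version: Optional[TaskVersion] = None,
    relabel: Optional[dict] = None,
) -> pd.Series:
    """Weight vector over design columns (canonical-HRF columns only)."""
    w = pd.Series(0.0, index=list(columns))
    if name == "parametric_outcome":
        col = "outcome_x_magnitude:hrf"
        if col not in w.index:
            raise ValueError(f"column {col} missing from design")
        w[col] = 1.0
        return w
    if version is None:
        raise ValueError(f"contrast {name!r} needs the task version")
    if name == "adaptive":
        high, low = version.high_feature, version.low_feature
    elif name == "aberrant":
        if relabel is None:
            raise ValueError("aberrant contrast needs a subjective relabel mapping")
        if relabel.get("tie"):
            warnings.warn(
                "subjective relabel tie; contrast uses the tie-broken mapping",
                UserWarning,
                stacklevel=2,
            )
        high, low = relabel["subjective_high"], relabel["subjective_low"]
    else:
        raise ValueError(f"unknown contrast {name!r}")
    for ct in CUE_TYPES:
        col = f"{ct}:hrf"
        if high in ct.split("_"):
            if col not in w.index:
                raise ValueError(f"column {col} missing from design")
            w[col] = 0.5
        elif low in ct.split("_"):
            if col not in w.index:
                raise ValueError(f"column {col} missing from design")
            w[col] = -0.5
    return w


# ---------------------------------------------------------------------------
# Fitting

@dataclass(eq=False)
class RunFit:
    design: DesignMatrix = field(repr=False)
    columns: list[str]
    betas: np.ndarray = field(repr=False)         # p x V
    sigma2: np.ndarray = field(repr=False)        # V
    cov_unscaled: np.ndarray = field(repr=False)  # p x p, (Xw' Xw)^-1
    rho: float = 0.0
    dof: int = 0
    dropped_columns: tuple = ()


def _check_rank(x: np.ndarray, names: Sequence[str]) -> None:
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    bad = [names[i] for i in np.nonzero(diag < tol)[0]]
    if bad:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; dependent columns: {bad}"
        )


def _bias_corrected_rho(x: np.ndarray, resid: np.ndarray) -> float:
    """Pooled lag-1 autocorrelation, corrected for the fitting projection.

    The raw residual autocorrelation r1 is biased (roughly by -p/n even
    for white noise) because residuals live in the projection complement
    of X.  Under AR(1) noise with parameter rho the expectation of r1 is
    g(rho) = tr(M A M Sigma(rho)) / tr(M Sigma(rho)), with M the residual
    projector and A the symmetrised lag-1 operator; the estimate solves
    g(rho) = r1 by bisection.
    """
    n = x.shape[0]
    denom = float(np.sum(resid * resid))
    if denom == 0:
        return 0.0
    r1 = float(np.sum(resid[1:] * resid[:-1]) / denom)
    m = np.eye(n) - x @ np.linalg.pinv(x)
    a = (np.eye(n, k=1) + np.eye(n, k=-1)) / 2.0
    mam = m @ a @ m

    powers = np.arange(n)

    def g(rho: float) -> float:
        sigma = linalg.toeplitz(rho ** powers)
        return float((mam * sigma).sum() / (m * sigma).sum())

    lo, hi = -0.95, 0.95
    glo, ghi = g(lo), g(hi)
    if r1 <= min(glo, ghi):
        return lo if glo < ghi else hi
    if r1 >= max(glo, ghi):
        return hi if ghi > glo else lo
    return float(optimize.brentq(lambda rho: g(rho) - r1, lo, hi, xtol=1e-4))


def _whiten(z: np.ndarray, rho: float) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    out[0] = z[0] * np.sqrt(1.0 - rho * rho)
    out[1:] = z[1:] - rho * z[:-1]
    return out


def _fit_run(design: DesignMatrix, y: np.ndarray, global_scale: bool) -> RunFit:
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != design.n_scans:
        raise ValueError(
            f"data has {y.shape[0]} scans but design has {design.n_scans}"
        )
    if global_scale:
        grand = y.mean()
        if grand <= 0:
            warnings.warn("non-positive grand mean; skipping global scaling")
        else:
            y = y * (100.0 / grand)

    frame = design.frame
    norms = np.abs(frame.to_numpy()).max(axis=0)
    keep = norms > 0
    columns = [c for c, k in zip(frame.columns, keep) if k]
    dropped = tuple(c for c, k in zip(frame.columns, keep) if not k)
    x = frame.to_numpy()[:, keep]
    _check_rank(x, columns)

    pinv = np.linalg.pinv(x)
    resid = y - x @ (pinv @ y)
    # residuals at numerical-noise level (perfect fit): no serial structure
    if np.sum(resid * resid) <= 1e-16 * np.sum(y * y):
        rho = 0.0
    else:
        rho = _bias_corrected_rho(x, resid)

    xw, yw = _whiten(x, rho), _whiten(y, rho)
    pinv_w = np.linalg.pinv(xw)
    betas = pinv_w @ yw
    resid_w = yw - xw @ betas
    dof = x.shape[0] - x.shape[1]
    sigma2 = (resid_w ** 2).sum(axis=0) / dof
    cov_unscaled = np.linalg.pinv(xw.T @ xw)
    return RunFit(
        design=design,
        columns=columns,
        betas=betas,
        sigma2=sigma2,
        cov_unscaled=cov_unscaled,
        rho=rho,
        dof=dof,
        dropped_columns=dropped,
    )


@dataclass(eq=False)
class ContrastResult:
    name: str
    value: np.ndarray      # V, averaged over runs
    se: np.ndarray         # V
    per_run: np.ndarray    # n_runs x V
    weights: list[pd.Series] = field(repr=False, default_factory=list)


class FirstLevelModel:
    """Voxelwise prewhitened GLM over one or more runs (SAT blocks).

    Parameters
    ----------
    designs : DesignMatrix or sequence of DesignMatrix
    data : array (n_scans, n_voxels) or sequence thereof, one per run
    version : TaskVersion, optional
        Needed for the adaptive/aberrant contrasts.
    relabels : sequence of dict, optional
        Per-run subjective relabel mappings (see
        :func:`satlab.scoring.subjective_relabel`) for the aberrant
        contrast.
    global_scale : bool
        Grand-mean scale each run's data to 100 before fitting.
    """

    def __init__(
        self,
        designs: Union[DesignMatrix, Sequence[DesignMatrix]],
        data,
        version: Optional[TaskVersion] = None,
        relabels: Optional[Sequence[dict]] = None,
        global_scale: bool = False,
    ):
        if isinstance(designs, DesignMatrix):
            designs = [designs]
            data = [data]
        self.designs = list(designs)
        self.data = [np.asarray(d, dtype=float) for d in data]
        if len(self.designs) != len(self.data):
            raise ValueError("one data array per design required")
        self.version = version
        self.relabels = list(relabels) if relabels is not None else None
        self.global_scale = global_scale

    @classmethod
    def from_subject(
        cls,
        log: SubjectLog,
        bold_runs: Sequence[np.ndarray],
        tr: float = TR_DEFAULT,
        global_scale: bool = True,
    ) -> "FirstLevelModel":
        """Build the model from a behavioural log plus per-block BOLD data."""
        from .scoring import subjective_relabel

        event_sets = screen_events(log)
        if len(bold_runs) != len(event_sets):
            raise ValueError("need one BOLD run per block")
        designs = [
            build_design(ev, n_scans=np.asarray(y).shape[0], tr=tr)
            for ev, y in zip(event_sets, bold_runs)
        ]
        relabels = [subjective_relabel(log, b) for b in range(1, len(event_sets) + 1)]
        return cls(designs, bold_runs, version=log.version,
                   relabels=relabels, global_scale=global_scale)

    def fit(self) -> "FirstLevelResults":
        runs = [
            _fit_run(d, y, self.global_scale) for d, y in zip(self.designs, self.data)
        ]
        return FirstLevelResults(self, runs)


class FirstLevelResults:
    """Fitted first-level GLM: betas, AR(1) estimates and contrasts."""

    def __init__(self, model: FirstLevelModel, runs: list[RunFit]):
        self.model = model
        self.runs = runs

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def rho(self) -> list[float]:
        return [r.rho for r in self.runs]

    def betas(self, run: int = 0) -> pd.DataFrame:
        r = self.runs[run]
        return pd.DataFrame(r.betas, index=r.columns)

    def contrast(
        self,
        spec: Union[str, ContrastSpec],
        relabel: Optional[Sequence[dict]] = None,
    ) -> ContrastResult:
        """Compute a contrast, averaged over runs.

        For the aberrant contrast the per-run weight assignment follows the
        block-specific subjective relabel mapping (``relabel`` argument, or
        the mappings stored on the model); a level may therefore flip sign
        between runs.
        """
        if isinstance(spec, str):
            spec = ContrastSpec(spec)
        relabels = list(relabel) if relabel is not None else self.model.relabels
        values, variances, weights = [], [], []
        for i, run in enumerate(self.runs):
            if spec.weights is not None:
                w = spec.weights.reindex(run.columns).fillna(0.0)
            else:
                rl = None
                if spec.name == "aberrant":
                    if relabels is None:
                        raise ValueError("aberrant contrast needs relabel mappings")
                    rl = relabels[i]
                w = contrast_weights(run.columns, spec.name, self.model.version, rl)
            wv = w.to_numpy()
            values.append(wv @ run.betas)
            variances.append((wv @ run.cov_unscaled @ wv) * run.sigma2)
            weights.append(w)
        per_run = np.vstack(values)
        value = per_run.mean(axis=0)
        se = np.sqrt(np.sum(variances, axis=0)) / self.n_runs
        return ContrastResult(spec.name, value, se, per_run, weights)

    def summary(self) -> pd.DataFrame:
        """Per-run fit summary: scans, columns, dropped columns, AR(1) rho."""
        rows = []
        for i, r in enumerate(self.runs):
            rows.append(
                {
                    "run": i + 1,
                    "n_scans": r.design.n_scans,
                    "n_columns": len(r.columns),
                    "dropped": ", ".join(r.dropped_columns),
                    "rho": r.rho,
                    "dof": r.dof,
                }
            )
        return pd.DataFrame(rows).set_index("run")


def fit_glm(y: np.ndarray, design: DesignMatrix, **kwargs) -> FirstLevelResults:
    """Fit a single-run voxelwise GLM (functional wrapper)."""
    return FirstLevelModel(design, y, **kwargs).fit()


def apply_contrast(
    result: FirstLevelResults,
    spec: Union[str, ContrastSpec],
    relabel: Optional[Sequence[dict]] = None,
) -> np.ndarray:
    """Voxel map of a contrast (functional wrapper around ``.contrast``)."""
    return result.contrast(spec, relabel=relabel).value


def simulate_bold(
    design: DesignMatrix,
    amplitudes: dict[str, float],
    noise_sd: float = 0.0,
    rho: float = 0.0,
    n_voxels: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Synthesize BOLD data ``X @ b + AR(1) noise`` for given column betas.

    ``amplitudes`` maps design column names to true beta values; all other
    betas are zero.  AR(1) noise has marginal SD ``noise_sd``.
    """
    if rng is None:
        rng = np.random.default_rng()
    frame = design.frame
    b = np.zeros(frame.shape[1])
    for name, amp in amplitudes.items():
        if name not in frame.columns:
            raise KeyError(f"unknown design column {name!r}")
        b[frame.columns.get_loc(name)] = amp
    signal = frame.to_numpy() @ b
    y = np.tile(signal[:, None], (1, n_voxels))
    if noise_sd > 0:
        n = design.n_scans
        e = np.empty((n, n_voxels))
        e[0] = rng.normal(0.0, noise_sd, n_voxels)
        innov_sd = noise_sd * np.sqrt(1.0 - rho * rho)
        innovations = rng.normal(0.0, innov_sd, (n - 1, n_voxels))
        for t in range(1, n):
            e[t] = rho * e[t - 1] + innovations[t - 1]
        y = y + e
    return y
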