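"""Group-level analysis of first-level contrast maps.

Voxelwise one-sample tests of the group mean contrast, with an optional
learning-measure covariate (centred, so the intercept stays the group
mean), spherical volumes of interest in millimetre space, and
familywise-error control by max-statistic permutation: sign-flipping for
the mean effect, covariate shuffling for the covariate effect.  The
covariate t statistic and the voxelwise Pearson r are linked by the
identity t^2 = r^2 (n-2) / (1-r^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from nibabel.affines import apply_affine

__all__ = [
    "VOISphere",
    "GroupModel",
    "GroupResults",
    "group_fit",
    "sphere_mask",
    "permutation_correct",
]

DEFAULT_VOI_RADIUS_MM = 8.0


@dataclass(frozen=True)
class VOISphere:
    """Spherical volume of interest in mm (scanner/MNI) coordinates."""

    center_mm: tuple[float, float, float]
    radius_mm: float = DEFAULT_VOI_RADIUS_MM


def sphere_mask(
    voi: VOISphere,
    shape: tuple[int, int, int],
    affine: np.ndarray,
) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within the sphere.

    Voxel indices are mapped to mm through the affine; a voxel belongs to
    the mask when the Euclidean distance from its centre to the sphere
    centre is at most the radius.
    """
    ijk = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    xyz = apply_affine(np.asarray(affine, dtype=float), ijk.reshape(-1, 3))
    d2 = ((xyz - np.asarray(voi.center_mm, dtype=float)) ** 2).sum(axis=1)
    mask = (d2 <= voi.radius_mm ** 2 + 1e-9).reshape(shape)
    if not mask.any():
        raise ValueError(
            f"sphere at {voi.center_mm} mm (r={voi.radius_mm}) contains no voxel centre"
        )
    return mask


class GroupModel:
    """One-sample group model with an optional subject covariate.

    Parameters
    ----------
    maps : array (n_subjects, ...) — one contrast map per subject; any
        trailing spatial shape is flattened internally.
    covariate : array (n_subjects,), optional — e.g. the explicit aberrant
        learning measure averaged over blocks.  Centred before fitting.
    """

    def __init__(self, maps: np.ndarray, covariate: Optional[Sequence[float]] = None):
        maps = np.asarray(maps, dtype=float)
        if maps.ndim < 2:
            raise ValueError("maps must be (n_subjects, n_voxels) or (n_subjects, *shape)")
        self.n_subjects = maps.shape[0]
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        self.spatial_shape = maps.shape[1:]
        self.maps = maps.reshape(self.n_subjects, -1)
        self.covariate = None
        self.constant_covariate = False
        if covariate is not None:
            c = np.asarray(covariate, dtype=float)
            if c.shape != (self.n_subjects,):
                raise ValueError("covariate length must equal the number of subjects")
            if np.ptp(c) == 0:
                warnings.warn("constant covariate; covariate tests skipped")
                self.constant_covariate = True
            else:
                self.covariate = c - c.mean()

    def fit(self) -> "GroupResults":
        y = self.maps
        n = self.n_subjects
        if self.covariate is None:
            x = np.ones((n, 1))
        else:
            x = np.column_stack([np.ones(n), self.covariate])
        k = x.shape[1]
        dof = n - k
        xtx_inv = np.linalg.inv(x.T @ x)
        betas = xtx_inv @ x.T @ y
        resid = y - x @ betas
        sigma2 = (resid ** 2).sum(axis=0) / dof
        # voxels fitted exactly (residuals at numerical-noise level): a zero
        # effect has t = 0, a non-zero one an infinite t
        y_scale = np.sqrt((y ** 2).mean(axis=0))
        degenerate = np.sqrt(sigma2) <= 1e-12 * np.maximum(y_scale, np.finfo(float).tiny)
        beta_zero = np.abs(betas) <= 1e-12 * np.maximum(y_scale, np.finfo(float).tiny)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
            t = betas / se
            t = np.where(degenerate & beta_zero, 0.0, t)
            t = np.where(degenerate & ~beta_zero, np.sign(betas) * np.inf, t)
        t_mean = t[0]
        if self.covariate is not None:
            t_cov = t[1]
            with np.errstate(divide="ignore", invalid="ignore"):
                r_cov = t_cov / np.sqrt(t_cov ** 2 + dof)
                r_cov = np.where(np.isinf(t_cov), np.sign(t_cov), r_cov)
            slope = betas[1]
        else:
            t_cov = r_cov = slope = None
        return GroupResults(
            model=self,
            mean=betas[0],
            slope=slope,
            t_mean=t_mean,
            t_cov=t_cov,
            r_cov=r_cov,
            dof=dof,
            sigma2=sigma2,
        )


@dataclass(eq=False)
class GroupResults:
    """Voxelwise group statistics plus permutation-based FWE correction."""

    model: GroupModel = field(repr=False)
    mean: np.ndarray = field(repr=False)
    slope: Optional[np.ndarray] = field(repr=False, default=None)
    t_mean: Optional[np.ndarray] = field(repr=False, default=None)
    t_cov: Optional[np.ndarray] = field(repr=False, default=None)
    r_cov: Optional[np.ndarray] = field(repr=False, default=None)
    dof: int = 0
    sigma2: Optional[np.ndarray] = field(repr=False, default=None)

    def reshape(self, stat: np.ndarray) -> np.ndarray:
        return stat.reshape(self.model.spatial_shape)

    def permutation_correct(
        self,
        statistic: str = "mean",
        n_perm: int = 1000,
        seed: int = 0,
    ) -> np.ndarray:
        """FWE-corrected p per voxel via the max-|t| null distribution.

        ``statistic='mean'`` builds the null by flipping the sign of each
        subject's map (one-sample t, exchangeable under symmetric H0);
        ``'covariate'`` shuffles the covariate across subjects.  The
        corrected p is the rank of each voxel's observed |t| within the
        null maxima: p = (1 + #{max_null >= |t|}) / (n_perm + 1).
        """
        if n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        rng = np.random.default_rng(seed)
        y = self.model.maps
        n = self.model.n_subjects

        if statistic == "mean":
            t_obs = np.abs(_one_sample_t(y))
            max_null = np.empty(n_perm)
            for j in range(n_perm):
                signs = rng.choice([-1.0, 1.0], size=n)
                max_null[j] = np.abs(_one_sample_t(signs[:, None] * y)).max()
        elif statistic == "covariate":
            if self.model.covariate is None:
                raise ValueError("no (non-constant) covariate in the model")
            c = self.model.covariate
            t_obs = np.abs(_covariate_t(y, c))
            max_null = np.empty(n_perm)
            for j in range(n_perm):
                max_null[j] = np.abs(_covariate_t(y, rng.permutation(c))).max()
        else:
            raise ValueError("statistic must be 'mean' or 'covariate'")

        exceed = (max_null[:, None] >= t_obs[None, :]).sum(axis=0)
        return (1.0 + exceed) / (n_perm + 1.0)

    def voi_summary(
        self,
        vois: Sequence[VOISphere],
        shape: tuple[int, int, int],
        affine: np.ndarray,
    ) -> pd.DataFrame:
        """Mean contrast per subject within each VOI sphere."""
        rows = []
        for voi in vois:
            mask = sphere_mask(voi, shape, affine).reshape(-1)
            vals = self.model.maps[:, mask].mean(axis=1)
            for i, v in enumerate(vals):
                rows.append(
                    {"voi": f"{voi.center_mm}_r{voi.radius_mm:g}",
                     "subject": i, "mean_contrast": float(v)}
                )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Peak-level summary of the group statistics."""
        rows = [
            {
                "statistic": "mean_effect",
                "peak_t": float(np.nanmax(np.abs(self.t_mean))),
                "peak_voxel": int(np.nanargmax(np.abs(self.t_mean))),
                "dof": self.dof,
            }
        ]
        if self.t_cov is not None:
            i = int(np.nanargmax(np.abs(self.t_cov)))
            rows.append(
                {
                    "statistic": "covariate",
                    "peak_t": float(np.abs(self.t_cov[i])),
                    "peak_voxel": i,
                    "dof": self.dof,
                    "peak_r": float(self.r_cov[i]),
                }
            )
        return pd.DataFrame(rows).set_index("statistic")

    def plot_covariate_scatter(self, voxel: int, ax=None):
        """Scatter of subject contrast values against the covariate."""
        import matplotlib.pyplot as plt

        if self.model.covariate is None:
            raise ValueError("model has no covariate")
        if ax is None:
            _, ax = plt.subplots()
        c = self.model.covariate
        v = self.model.maps[:, voxel]
        ax.scatter(c, v)
        ax.set_xlabel("covariate (centred)")
        ax.set_ylabel("contrast value")
        ax.set_title(f"voxel {voxel}: r = {self.r_cov[voxel]:.2f}")
        return ax


def _one_sample_t(y: np.ndarray) -> np.ndarray:
    n = y.shape[0]
    mean = y.mean(axis=0)
    sd = y.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return mean / (sd / np.sqrt(n))


def _covariate_t(y: np.ndarray, c_centered: np.ndarray) -> np.ndarray:
    n = y.shape[0]
    css = float(c_centered @ c_centered)
    slope = (c_centered @ y) / css
    fitted = np.outer(c_centered, slope) + y.mean(axis=0)
    resid = y - fitted
    sigma2 = (resid ** 2).sum(axis=0) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return slope / np.sqrt(sigma2 / css)


def group_fit(maps: np.ndarray, covariate: Optional[Sequence[float]] = None) -> GroupResults:
    """Fit the group model (functional wrapper)."""
    return GroupModel(maps, covariate=covariate).fit()


def permutation_correct(
    maps: np.ndarray,
    covariate: Optional[Sequence[float]] = None,
    statistic: str = "mean",
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """FWE-corrected p values (functional wrapper)."""
    return group_fit(maps, covariate=covariate).permutation_correct(
        statistic=statistic, n_perm=n_perm, seed=seed
    )
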