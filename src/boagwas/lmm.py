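"""VanRaden kinship, variance components, and mixed-model Wald tests.

The association models are single-marker linear mixed models

    y = X b + SNP a + Z g + e        (SNP model)
    y = X b + BOA c + Z g + e        (BOA model)
    y = X b + SNP a + BOA c + Z g + e  (joint model)

with g ~ N(0, G sigma_g^2), e ~ N(0, I sigma_e^2), Z = I (one record per
animal), and G the VanRaden genomic relationship matrix

    G = Z_c Z_c' / (2 sum_i p_i (1 - p_i)),   Z_c = dosage - 2 p.

Each tested marker uses the leave-one-chromosome-out (LOCO) G built without
the marker's own chromosome.  Fitting exploits the spectral decomposition
G = U D U': rotating y and the design by U' diagonalizes the covariance to
sigma^2 diag(h^2 lambda_i + 1 - h^2), so the likelihood profiles to a 1-D
search over the heritability ratio h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)
with closed-form GLS estimates at each h^2.  Maximum likelihood is the
default criterion (REML available); variance components are re-estimated
under the full per-marker model by default.

Wald tests: single effects use (beta/se)^2 ~ chi2(1); the joint SNP+BOA test
uses beta' Cov(beta)^{-1} beta over the two marker coefficients ~ chi2(2).
A BOA column that is numerically collinear with the SNP column (or with the
covariates) is dropped, the test degrees of freedom reduced, and the result
flagged as aliased.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2 as _chi2

from .containers import AncestryMatrix, GenotypeMatrix

#: Floor applied to non-positive GRM eigenvalues before fitting.
EIGEN_FLOOR = 1e-10
#: Relative tolerance of the pivoted aliasing check on marker columns.
ALIASING_TOL = 1e-8

MODEL_LABELS = {"snp": "SNP", "boa": "BOA", "joint": "SNP+BOA"}


class LmmError(ValueError):
    pass


class ZeroDenominatorError(LmmError):
    """All markers monomorphic: the VanRaden scaling denominator is zero."""


class RankDeficientError(LmmError):
    """The covariate matrix X is rank deficient."""


@dataclass
class GRMEigen:
    """A genomic relationship matrix with its spectral decomposition."""

    G: np.ndarray
    denominator: float
    eigenvalues: np.ndarray  # non-increasing
    eigenvectors: np.ndarray  # columns match eigenvalues
    excluded_chromosome: int | None = None

    @property
    def n(self) -> int:
        return self.G.shape[0]

    def floored_eigenvalues(self) -> np.ndarray:
        return np.maximum(self.eigenvalues, EIGEN_FLOOR)

    @classmethod
    def identity(cls, n: int) -> "GRMEigen":
        """Identity relationship (unrelated individuals); in this limit the
        mixed model collapses to ordinary least squares."""
        return cls(G=np.eye(n), denominator=float(n), eigenvalues=np.ones(n),
                   eigenvectors=np.eye(n))


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    loglik: float
    method: str = "ml"

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


@dataclass
class AssocResult:
    """Per-marker association result for one model."""

    model: str
    beta_snp: float = np.nan
    se_snp: float = np.nan
    beta_boa: float = np.nan
    se_boa: float = np.nan
    wald: float = np.nan
    df: int = 0
    p: float = np.nan
    h2_at_marker: float = np.nan
    aliased: bool = False
    p_snp: float = np.nan
    p_boa: float = np.nan


def _grm_from_centered(z: np.ndarray, denom: float, excluded=None) -> GRMEigen:
    if denom <= 0:
        raise ZeroDenominatorError("VanRaden denominator 2*sum p(1-p) is zero")
    g = (z @ z.T) / denom
    g = (g + g.T) / 2.0
    lam, vec = np.linalg.eigh(g)
    order = np.argsort(lam)[::-1]
    return GRMEigen(
        G=g, denominator=denom, eigenvalues=lam[order], eigenvectors=vec[:, order],
        excluded_chromosome=excluded,
    )


def vanraden_grm(genotypes: GenotypeMatrix, marker_mask=None) -> GRMEigen:
    """VanRaden GRM from sample-estimated frequencies.

    Missing dosages are mean-imputed (2p) before centering, so imputed cells
    contribute zero to Z.  Requires at least 2 markers in the subset.
    """
    d = genotypes.imputed_dosage()
    if marker_mask is not None:
        d = d[:, np.asarray(marker_mask)]
    if d.shape[1] < 1:
        raise LmmError("need at least 1 marker to build a GRM")
    p = d.mean(axis=0) / 2.0
    z = d - 2.0 * p
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    return _grm_from_centered(z, denom)


def loco_grms(genotypes: GenotypeMatrix, marker_mask=None) -> dict[int, GRMEigen]:
    """Leave-one-chromosome-out GRMs, one per chromosome present.

    G_loco(c) is built from all markers not on chromosome c, with the
    VanRaden denominator recomputed on that marker subset.  Computed by
    subtracting each chromosome's numerator from the genome-wide numerator.
    """
    d = genotypes.imputed_dosage()
    chrom = genotypes.markers["chromosome"].to_numpy()
    if marker_mask is not None:
        mask = np.asarray(marker_mask)
        d = d[:, mask]
        chrom = chrom[mask]
    chroms = np.unique(chrom)
    if len(chroms) < 2:
        raise LmmError("LOCO needs markers on at least 2 chromosomes")
    p = d.mean(axis=0) / 2.0
    z = d - 2.0 * p
    per_p = p * (1.0 - p)
    full_num = z @ z.T
    full_den = float(2.0 * per_p.sum())
    out: dict[int, GRMEigen] = {}
    for c in chroms:
        on_c = chrom == c
        zc = z[:, on_c]
        num = full_num - zc @ zc.T
        den = full_den - float(2.0 * per_p[on_c].sum())
        if den <= 0:
            raise ZeroDenominatorError(f"all polymorphic markers sit on chromosome {c}")
        g = (num + num.T) / 2.0 / den
        lam, vec = np.linalg.eigh(g)
        order = np.argsort(lam)[::-1]
        out[int(c)] = GRMEigen(
            G=g, denominator=den, eigenvalues=lam[order], eigenvectors=vec[:, order],
            excluded_chromosome=int(c),
        )
    return out


def group_design(samples: pd.DataFrame) -> np.ndarray:
    """Fixed-effect design for the collection group: intercept + dummies
    (first group as reference)."""
    codes = samples["collection_group"].astype("category").cat.codes.to_numpy()
    k = codes.max() + 1
    x = np.ones((len(codes), 1))
    if k > 1:
        dummies = np.zeros((len(codes), k - 1))
        for j in range(1, k):
            dummies[codes == j, j - 1] = 1.0
        x = np.hstack([x, dummies])
    return x


def _profile(h2, lam, ry, rx, method):
    """Profile log-likelihood at h2 with closed-form GLS and scale."""
    n, p = rx.shape
    w = h2 * lam + (1.0 - h2)
    rxw = rx / w[:, None]
    xtwx = rx.T @ rxw
    beta = np.linalg.solve(xtwx, rxw.T @ ry)
    resid = ry - rx @ beta
    rss = float((resid**2 / w).sum())
    logw = float(np.log(w).sum())
    if method == "reml":
        sigma2 = rss / (n - p)
        _, logdet = np.linalg.slogdet(xtwx)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + logw + logdet + (n - p))
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logw + n)
    return ll, beta, sigma2, xtwx


def _optimize_h2(lam, ry, rx, method, tol=1e-8):
    def neg(h2):
        return -_profile(h2, lam, ry, rx, method)[0]

    res = minimize_scalar(neg, bounds=(0.0, 1.0 - 1e-6), method="bounded",
                          options={"xatol": tol})
    h2 = float(res.x)
    ll = -float(res.fun)
    ll0 = _profile(0.0, lam, ry, rx, method)[0]
    # Tie rule: a flat profile (e.g. G = I) resolves to the h2 = 0 boundary.
    if ll0 >= ll - 1e-8:
        return 0.0, ll0
    if not np.isfinite(ll):
        raise LmmError("non-finite profile likelihood")
    return h2, ll


def fit_null_lmm(y, X, grm: GRMEigen, method: str = "ml",
                 fixed_h2: float | None = None) -> VarianceComponents:
    """Variance components of the null model y = Xb + g + e by spectral ML.

    The likelihood is profiled over h2 in [0, 1 - 1e-6] via bounded 1-D
    search (tolerance 1e-8); sigma^2 is closed-form at each h2.  ``method``
    selects ML (default) or REML; ``fixed_h2`` skips the search.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n < p + 2:
        raise LmmError(f"need n >= p + 2 observations, got n={n}, p={p}")
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficientError("covariate matrix X is rank deficient")
    lam = grm.floored_eigenvalues()
    u = grm.eigenvectors
    ry, rx = u.T @ y, u.T @ X
    if fixed_h2 is not None:
        h2 = float(fixed_h2)
        ll = _profile(h2, lam, ry, rx, method)[0]
    else:
        h2, ll = _optimize_h2(lam, ry, rx, method)
    _, _, sigma2, _ = _profile(h2, lam, ry, rx, method)
    if not np.isfinite(ll):
        raise LmmError("non-finite likelihood at the optimum")
    return VarianceComponents(sigma_g2=h2 * sigma2, sigma_e2=(1 - h2) * sigma2,
                              loglik=ll, method=method)


def _seq_alias(rx, cols, tol=ALIASING_TOL):
    """Sequentially keep marker columns not in the span of what precedes them.

    Returns (kept design, keep flags).  The check is a least-squares residual
    norm against the running design with relative tolerance ``tol``; the
    later column loses (BOA in the joint model)."""
    design = rx
    keep = []
    for col in cols.T:
        sol, *_ = np.linalg.lstsq(design, col, rcond=None)
        resid = col - design @ sol
        norm = np.linalg.norm(col)
        ok = norm > 0 and np.linalg.norm(resid) > tol * norm
        keep.append(ok)
        if ok:
            design = np.column_stack([design, col])
    return design, np.array(keep, dtype=bool)


def _assoc_rotated(lam, ry, rx, rcols, model, method="ml", reestimate=True,
                   null_h2=None, fixed_h2=None, aliasing_tol=ALIASING_TOL) -> AssocResult:
    label = MODEL_LABELS[model]
    design, keep = _seq_alias(rx, rcols, aliasing_tol)
    k = int(keep.sum())
    aliased = not keep.all()
    if k == 0:
        # monomorphic / fully collinear covariable: no testable effect
        return AssocResult(model=label, aliased=aliased)

    if fixed_h2 is not None:
        h2 = float(fixed_h2)
    elif reestimate:
        h2, _ = _optimize_h2(lam, ry, design, method)
    else:
        h2 = float(null_h2)
    _, beta, sigma2, xtwx = _profile(h2, lam, ry, design, method)
    cov = sigma2 * np.linalg.inv(xtwx)
    p_cov = rx.shape[1]
    b = beta[p_cov:]
    cb = cov[p_cov:, p_cov:]
    se = np.sqrt(np.diag(cb))

    res = AssocResult(model=label, h2_at_marker=h2, aliased=aliased)
    # map kept columns back to their roles
    roles = ["snp"] if model == "snp" else ["boa"] if model == "boa" else ["snp", "boa"]
    kept_roles = [r for r, k_ in zip(roles, keep) if k_]
    for j, role in enumerate(kept_roles):
        wald_j = (b[j] / se[j]) ** 2
        p_j = chi2_sf(wald_j, 1)
        if role == "snp":
            res.beta_snp, res.se_snp, res.p_snp = float(b[j]), float(se[j]), p_j
        else:
            res.beta_boa, res.se_boa, res.p_boa = float(b[j]), float(se[j]), p_j

    if model == "joint" and k == 2:
        wald = float(b @ np.linalg.solve(cb, b))
        df = 2
    else:
        wald = float((b[0] / se[0]) ** 2)
        df = 1
    res.wald, res.df, res.p = wald, df, chi2_sf(wald, df)
    return res


def assoc_test(y, X, marker_cols, grm: GRMEigen, model: str = "snp",
               method: str = "ml", reestimate: bool = True,
               null_h2: float | None = None, fixed_h2: float | None = None,
               aliasing_tol: float = ALIASING_TOL) -> AssocResult:
    """Mixed-model Wald test of one marker under one model.

    ``marker_cols`` holds the marker covariables aligned to y: one column
    (SNP or BOA dosage) for the single-effect models, two columns
    (SNP, BOA) for the joint model.  ``grm`` should be the LOCO matrix for
    the marker's chromosome.  Variance components are re-estimated under the
    full model by default; pass ``reestimate=False`` with ``null_h2`` to
    reuse a per-chromosome null estimate, or ``fixed_h2`` to pin h2 (0 gives
    the ordinary-least-squares limit when G = I).
    """
    if model not in MODEL_LABELS:
        raise ValueError(f"unknown model {model!r}")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cols = np.asarray(marker_cols, dtype=float)
    if cols.ndim == 1:
        cols = cols[:, None]
    expected = 2 if model == "joint" else 1
    if cols.shape[1] != expected:
        raise ValueError(f"model {model!r} expects {expected} marker column(s)")
    lam = grm.floored_eigenvalues()
    u = grm.eigenvectors
    return _assoc_rotated(lam, u.T @ y, u.T @ X, u.T @ cols, model, method,
                          reestimate, null_h2, fixed_h2, aliasing_tol)


def chi2_sf(w: float, df: int) -> float:
    """Upper-tail chi-square probability for a Wald statistic."""
    if w < 0:
        raise ValueError("Wald statistic must be non-negative")
    return float(_chi2.sf(w, df))


def association_scan(
    y,
    X,
    genotypes: GenotypeMatrix,
    ancestry: AncestryMatrix | None = None,
    grms: Mapping[int, GRMEigen] | GRMEigen | None = None,
    models: tuple[str, ...] = ("snp", "boa", "joint"),
    method: str = "ml",
    variance_estimation: str = "marker",
    fixed_h2: float | None = None,
    aliasing_tol: float = ALIASING_TOL,
) -> pd.DataFrame:
    """Scan every marker under the requested models; returns a tidy frame.

    ``grms`` is either a dict of LOCO matrices keyed by chromosome (the
    default produced by :func:`loco_grms`) or a single GRM used genome-wide.
    ``variance_estimation`` is ``"marker"`` (re-fit h2 under each full
    per-marker model, the default) or ``"chromosome"`` (fit the null once
    per chromosome and reuse its h2).  Models needing BOA dosages require
    ``ancestry`` aligned to the genotypes.
    """
    needs_boa = any(m in ("boa", "joint") for m in models)
    if needs_boa and ancestry is None:
        raise ValueError("BOA/joint models need an ancestry matrix")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if grms is None:
        grms = loco_grms(genotypes)
    dos = genotypes.imputed_dosage()
    boa = ancestry.boa_dosage.astype(float) if ancestry is not None else None
    chrom = genotypes.markers["chromosome"].to_numpy()
    mk = genotypes.markers

    rows = []
    for c in np.unique(chrom):
        grm = grms if isinstance(grms, GRMEigen) else grms[int(c)]
        lam = grm.floored_eigenvalues()
        u = grm.eigenvectors
        ry, rx = u.T @ y, u.T @ X
        idx = np.flatnonzero(chrom == c)
        rg = u.T @ dos[:, idx]
        rb = u.T @ boa[:, idx] if boa is not None else None
        null_h2 = None
        reestimate = variance_estimation == "marker"
        if not reestimate and fixed_h2 is None:
            null_h2 = fit_null_lmm(y, X, grm, method=method).h2
        for k, j in enumerate(idx):
            for model in models:
                if model == "snp":
                    rcols = rg[:, [k]]
                elif model == "boa":
                    rcols = rb[:, [k]]
                else:
                    rcols = np.column_stack([rg[:, k], rb[:, k]])
                res = _assoc_rotated(lam, ry, rx, rcols, model, method,
                                     reestimate, null_h2, fixed_h2, aliasing_tol)
                rows.append(
                    {
                        "marker_id": mk["marker_id"].iloc[j],
                        "chromosome": int(mk["chromosome"].iloc[j]),
                        "position_bp": int(mk["position_bp"].iloc[j]),
                        "model": res.model,
                        "beta_snp": res.beta_snp,
                        "se_snp": res.se_snp,
                        "beta_boa": res.beta_boa,
                        "se_boa": res.se_boa,
                        "wald": res.wald,
                        "df": res.df,
                        "p": res.p,
                        "h2_at_marker": res.h2_at_marker,
                        "aliased": res.aliased,
                        "p_snp": res.p_snp,
                        "p_boa": res.p_boa,
                    }
                )
    return pd.DataFrame(rows)
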