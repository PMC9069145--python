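"""Association scans of probe-level CNV dosage against continuous traits.

Traits are prepared once (rank-based inverse normal transform, then
residualization on sex, age, age^2, genotyping batch, and principal
components) and each probe is then tested by simple linear regression of
the prepared trait on its T-allele dosage, separately under the mirror,
duplication-only, and deletion-only encodings. Effects are reported on the
T-allele scale (sign flipped when the file-set's A1 allele is "A").
Multiple testing is handled through the effective number of independent
tests (Neff) among the highly correlated CNV-proxy probes, and independent
signals per trait are isolated by stepwise conditional analysis: the lead
probe's dosage is regressed out of the trait and the scan repeated until
nothing remains genome-wide significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import MISSING, ModelGenotypes


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PreparedTrait:
    name: str
    values: pd.Series  # residualized (optionally inverse-normal) values per sample
    sex_restricted: str | None = None


@dataclass
class NeffEstimate:
    model: str
    n_probes_tested: int
    n_effective: int
    method: str


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def inverse_normal_transform(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform, Blom offset by default.

    Maps value of rank r (ties averaged) to Phi^-1((r - offset)/(n + 1 - 2*offset)).
    Strictly monotone in the input order; NaNs are propagated.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    xf = x[finite]
    if np.unique(xf).size < 2:
        raise ValueError("inverse normal transform needs >= 2 distinct finite values")
    ranks = stats.rankdata(xf, method="average")
    n = xf.size
    out = np.full_like(x, np.nan)
    out[finite] = stats.norm.ppf((ranks - offset) / (n + 1 - 2 * offset))
    return out


def _design_matrix(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    if isinstance(covariates, pd.DataFrame):
        cov = covariates
        if "batch" in cov.columns:  # categorical genotyping batch -> dummies
            cov = pd.get_dummies(cov, columns=["batch"], drop_first=True, dtype=float)
        mat = cov.to_numpy(dtype=float)
    else:
        mat = np.asarray(covariates, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
    return np.column_stack([np.ones(n), mat])


def residualize(
    trait: pd.Series | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    name: str = "trait",
    sex_restricted: str | None = None,
) -> PreparedTrait:
    """OLS residuals of the trait on an intercept plus covariates.

    Constant and linearly dependent covariate columns are dropped with a
    warning rather than raising, so routine covariate files with redundant
    columns (e.g., age and age^2 on a restricted age range) stay usable.
    """
    if isinstance(trait, pd.Series):
        index, y = trait.index, trait.to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
        index = pd.RangeIndex(len(y))
    X = _design_matrix(covariates, len(y))

    keep = [0]
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) > 0:
            keep.append(j)
    if len(keep) < X.shape[1]:
        warnings.warn(f"dropping {X.shape[1] - len(keep)} constant covariate column(s)")
    X = X[:, keep]
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    dep = diag < 1e-10 * max(diag.max(), 1.0)
    if dep.any():
        warnings.warn(f"dropping {int(dep.sum())} linearly dependent covariate column(s)")
        X = X[:, ~dep]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return PreparedTrait(name=name, values=pd.Series(resid, index=index), sex_restricted=sex_restricted)


def prepare_trait(
    raw: pd.Series,
    covariates: pd.DataFrame,
    inverse_normal: bool = True,
    name: str | None = None,
) -> PreparedTrait:
    """Inverse normal transform (optional) then residualize on the covariates."""
    values = raw.dropna()
    if inverse_normal:
        values = pd.Series(inverse_normal_transform(values.to_numpy()), index=values.index)
    cov = covariates.loc[values.index]
    return residualize(values, cov, name=name or str(raw.name))


def pairwise_r2(dosage: np.ndarray) -> np.ndarray:
    """Pairwise squared correlation between probe rows, pairwise-complete
    over missing cells; undefined pairs (zero variance) are returned as 0."""
    X = dosage.astype(np.float64)
    M = (dosage != MISSING).astype(np.float64)
    X = X * M
    N = M @ M.T
    Sx = X @ M.T
    Sxx = (X * X) @ M.T
    Sxy = X @ X.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = Sxy - Sx * Sx.T / N
        vx = Sxx - Sx**2 / N
        vy = vx.T
        r2 = cov**2 / (vx * vy)
    r2[~np.isfinite(r2)] = 0.0
    return r2


def prune_probes(
    geno: ModelGenotypes,
    r2_cap: float = 0.9999,
    window: int = 500,
    step: int = 250,
) -> np.ndarray:
    """Greedy left-to-right r^2 pruning in sliding probe-count windows.

    Within each window of ``window`` probes (advanced by ``step``), later
    probes correlated above ``r2_cap`` with an earlier retained probe are
    dropped. Zero-variance probes are removed first. Windows never span
    chromosomes. Returns retained row indices.
    """
    if geno.dosage.shape[1] < 2:
        raise ValueError("pruning needs >= 2 samples")
    keep = np.ones(len(geno.probes), dtype=bool)
    obs = geno.dosage != MISSING
    x = geno.dosage.astype(float)
    mean = np.where(obs, x, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        var = np.nanvar(mean, axis=1)
    keep &= np.nan_to_num(var) > 0

    chroms = geno.probes.chrom
    for chrom in pd.unique(chroms):
        rows = np.flatnonzero(chroms == chrom)
        start = 0
        while True:
            win = rows[start : start + window]
            if win.size >= 2:
                active = win[keep[win]]
                if active.size >= 2:
                    r2 = pairwise_r2(geno.dosage[active])
                    local_keep = np.ones(active.size, dtype=bool)
                    for i in range(active.size):
                        if not local_keep[i]:
                            continue
                        hit = r2[i, i + 1 :] > r2_cap
                        local_keep[i + 1 :][hit] = False
                    keep[active[~local_keep]] = False
            if start + window >= rows.size:
                break
            start += step
    return np.flatnonzero(keep)


def estimate_neff(geno: ModelGenotypes, variance_explained: float = 0.995) -> NeffEstimate:
    """Effective number of tests via per-chromosome eigen-decomposition.

    For each chromosome the probe correlation matrix (missing dosages
    mean-imputed per probe) is decomposed and the count of leading
    eigenvalues needed to reach ``variance_explained`` of the total variance
    is accumulated (simpleM-style).
    """
    if len(geno.probes) == 0:
        raise ValueError("empty probe set")
    chroms = geno.probes.chrom
    total = 0
    for chrom in pd.unique(chroms):
        rows = np.flatnonzero(chroms == chrom)
        x = geno.dosage[rows].astype(float)
        miss = geno.dosage[rows] == MISSING
        if miss.any():
            xm = np.where(miss, np.nan, x)
            means = np.nanmean(xm, axis=1)
            x = np.where(miss, means[:, None], x)
        sd = x.std(axis=1)
        x = x[sd > 0]
        if x.shape[0] == 0:
            continue
        corr = np.corrcoef(x)
        if corr.ndim == 0:
            total += 1
            continue
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        eig = np.clip(eig, 0.0, None)
        csum = np.cumsum(eig) / eig.sum()
        total += int(np.searchsorted(csum, variance_explained) + 1)
    total = max(total, 1)
    return NeffEstimate(
        model=geno.model,
        n_probes_tested=len(geno.probes),
        n_effective=total,
        method=f"per-chromosome eigen, {variance_explained:.3%} variance",
    )


def _align(geno: ModelGenotypes, trait: PreparedTrait) -> tuple[np.ndarray, np.ndarray]:
    """Column indices into geno.samples and the matching trait values."""
    trait_idx = {s: i for i, s in enumerate(trait.values.index)}
    cols, vals = [], []
    y = trait.values.to_numpy(dtype=float)
    for j, s in enumerate(geno.samples):
        i = trait_idx.get(s)
        if i is not None and np.isfinite(y[i]):
            cols.append(j)
            vals.append(y[i])
    if not cols:
        raise ValueError("no overlapping samples between genotypes and trait")
    return np.asarray(cols), np.asarray(vals)


def run_scan(geno: ModelGenotypes, trait: PreparedTrait) -> pd.DataFrame:
    """Per-probe simple linear regression of the prepared trait on dosage.

    The regression runs on the A1-allele dosage recorded in the file set and
    the reported beta is homogenized to the T scale (multiplied by -1 when
    A1 is "A"). Probes with fewer than two dosage classes among phenotyped
    samples are flagged ``untestable`` with NaN statistics.
    """
    cols, y = _align(geno, trait)
    d = geno.dosage[:, cols]
    obs = d != MISSING
    a_first = geno.a1 == "A"
    x = np.where(a_first[:, None], 2 - d, d).astype(np.float64)
    x[~obs] = 0.0
    m = obs.astype(np.float64)

    nm = m.sum(axis=1)
    sx = x.sum(axis=1)
    sy = m @ y
    sxx = (x * x).sum(axis=1)
    sxy = x @ y
    syy = m @ (y * y)
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx_c = sxx - sx**2 / nm
        sxy_c = sxy - sx * sy / nm
        syy_c = syy - sy**2 / nm
        beta_raw = sxy_c / sxx_c
        dof = nm - 2
        sse = np.clip(syy_c - beta_raw * sxy_c, 0.0, None)
        se = np.sqrt(sse / dof / sxx_c)
        tstat = beta_raw / se
    untestable = (nm < 3) | (sxx_c <= 1e-9)
    pvals = np.full(len(geno.probes), np.nan)
    ok = ~untestable & np.isfinite(tstat)
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), dof[ok])
    np.clip(pvals, np.nextafter(0, 1), 1.0, out=pvals)
    untestable |= ~ok

    beta_t = np.where(a_first, -beta_raw, beta_raw)
    out = pd.DataFrame(
        {
            "probe_id": geno.probes.probe_ids,
            "chrom": geno.probes.chrom,
            "pos": geno.probes.pos,
            "model": geno.model,
            "trait": trait.name,
            "beta": np.where(untestable, np.nan, beta_t),
            "se": np.where(untestable, np.nan, se),
            "p": np.where(untestable, np.nan, pvals),
            "n_used": nm.astype(int),
            "a1": geno.a1,
            "untestable": untestable,
        }
    )
    return out


def _pick_lead(results: pd.DataFrame) -> pd.Series:
    testable = results[~results["untestable"]]
    pmin = testable["p"].min()
    tied = testable[testable["p"] == pmin]
    return tied.sort_values(["chrom", "pos"]).iloc[0]


def stepwise_conditional(
    geno: ModelGenotypes,
    trait: PreparedTrait,
    gw_threshold: float,
    max_rounds: int = 20,
) -> pd.DataFrame:
    """Iteratively regress out the lead probe's dosage and rescan.

    Stops when no testable probe remains below ``gw_threshold``; returns the
    leads in discovery order with their round-specific statistics. Missing
    lead dosages are mean-imputed for the conditioning regression only.
    """
    cols, y = _align(geno, trait)
    current = pd.Series(y, index=[geno.samples[j] for j in cols])
    leads = []
    for rnd in range(max_rounds + 1):
        scan = run_scan(geno, PreparedTrait(name=trait.name, values=current))
        testable = scan[~scan["untestable"]]
        if testable.empty or testable["p"].min() > gw_threshold:
            break
        if rnd == max_rounds:
            raise ConvergenceError(
                f"conditional analysis for {trait.name!r} did not converge in "
                f"{max_rounds} rounds; min p = {testable['p'].min():.3e} at "
                f"{_pick_lead(scan)['probe_id']}"
            )
        lead = _pick_lead(scan)
        row = lead.copy()
        row["round"] = rnd + 1
        leads.append(row)
        g = geno.dosage[geno.probes.loc_of(lead["probe_id"]), cols].astype(float)
        g[g == MISSING] = np.nan
        g = np.where(np.isnan(g), np.nanmean(g), g)
        prepared = residualize(current.to_numpy(), g)
        current = pd.Series(prepared.values.to_numpy(), index=current.index)
    if not leads:
        return pd.DataFrame(columns=list(run_scan(geno, trait).columns) + ["round"])
    return pd.DataFrame(leads).reset_index(drop=True)
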