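"""Burden-recurrence models and genome-wide recurrence-association scans.

The burden predictor is log2(altered probe count + 1), so the exponential
of its coefficient is an odds ratio per doubling of altered probes. The
pseudo-count accommodates CNV-free tumors. Significance is assessed by
likelihood-ratio tests against the model without the term of interest;
odds-ratio confidence intervals are Wald intervals. Per-probe scans enter
the three-level probe status as a categorical factor (reference: normal)
and control dependent multiple testing with Benjamini-Yekutieli; per-gene
scans binarize gene status and use Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import ProbeMap

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "likelihood_ratio_test",
    "adjust_pvalues",
    "AssociationResult",
    "burden_association",
    "per_probe_scan",
    "map_genes_to_status",
    "per_gene_scan",
    "build_design",
]

_MAX_ABS_ETA = 30.0  # linear predictors beyond this indicate separation


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares."""

    coef: np.ndarray
    se: np.ndarray
    loglik: float
    deviance: float
    n_obs: int
    columns: list[str]
    converged: bool
    separated: bool

    def wald_ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        i = self.columns.index(name)
        z = stats.norm.ppf(0.5 + level / 2.0)
        return (self.coef[i] - z * self.se[i], self.coef[i] + z * self.se[i])

    def odds_ratio(self, name: str) -> float:
        return float(np.exp(self.coef[self.columns.index(name)]))


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    columns: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit a binary logistic regression by IRLS.

    Converges on relative deviance change below ``tol``. Complete or
    quasi-complete separation is detected (diverging linear predictor
    with perfectly classified observations) and flagged rather than
    raised; coefficients then sit at the iteration cap and odds ratios
    should be treated as infinite sentinels.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if columns is None:
        columns = [f"x{i}" for i in range(p)]
    if n <= p:
        raise ValueError(f"n={n} observations for p={p} parameters")
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all() or len(classes) < 2:
        raise ValueError("outcome must contain both classes 0 and 1")

    beta = np.zeros(p)
    dev_old = np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_MAX_ABS_ETA * 2, _MAX_ABS_ETA * 2)
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        beta_new, *_ = np.linalg.lstsq(X.T @ WX, X.T @ (w * z), rcond=None)
        beta = beta_new
        dev = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
        if np.isfinite(dev_old) and abs(dev_old - dev) <= tol * (abs(dev) + 0.1):
            converged = True
            dev_old = dev
            break
        dev_old = dev

    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700))), 1e-12, 1 - 1e-12)
    # separation: diverging predictor, or every observation classified with
    # essentially probability one (all residual probabilities < 1e-6)
    fitted_margin = np.where(y == 1, mu, 1.0 - mu)
    separated = bool(np.max(np.abs(eta)) > _MAX_ABS_ETA
                     or np.min(fitted_margin) > 1.0 - 1e-6)
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    loglik = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    return LogisticFit(
        coef=beta, se=se, loglik=loglik, deviance=-2.0 * loglik, n_obs=n,
        columns=list(columns), converged=converged, separated=separated,
    )


def likelihood_ratio_test(full: LogisticFit, reduced: LogisticFit) -> tuple[float, int, float]:
    """LRT of nested logistic models: statistic, df, chi-square p-value."""
    if reduced.n_obs != full.n_obs:
        raise ValueError("models fit on different observations")
    if len(reduced.columns) >= len(full.columns):
        raise ValueError("reduced model is not nested in full model")
    if not set(reduced.columns) <= set(full.columns):
        raise ValueError("reduced model has terms absent from full model")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = len(full.columns) - len(reduced.columns)
    return stat, df, float(stats.chi2.sf(stat, df))


def adjust_pvalues(pvalues: np.ndarray, method: str = "BH") -> np.ndarray:
    """Step-up false-discovery-rate adjustment.

    "BH" is Benjamini-Hochberg; "BY" is Benjamini-Yekutieli, whose
    adjusted values carry the harmonic-sum factor c(m) = sum 1/i, valid
    under arbitrary dependence between tests. Output is monotone in rank
    and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "BY": "fdr_by"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


@dataclass
class AssociationResult:
    predictor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    lrt_stat: float
    lrt_df: int
    p_value: float
    adjusted_p: float | None = None
    adjustment: str = "none"
    covariates: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor, "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "lrt_stat": self.lrt_stat, "lrt_df": self.lrt_df,
            "p_value": self.p_value, "adjusted_p": self.adjusted_p,
            "adjustment": self.adjustment,
            "covariates": ";".join(self.covariates), "flags": ";".join(self.flags),
        }


def build_design(
    clinical: pd.DataFrame,
    covariates: list[str],
    merge_grades_1: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with intercept) from clinical covariates.

    Categorical covariates are dummy-coded against their first observed
    level; ``merge_grades_1`` collapses grades 1a and 1b (used in
    per-type analyses where 1b is rare). Age enters in decades so its
    coefficient is an OR per 10 years. Constant columns are dropped.
    """
    cols: list[np.ndarray] = [np.ones(len(clinical))]
    names = ["intercept"]
    for cov in covariates:
        if cov == "age":
            cols.append(clinical["age"].to_numpy(dtype=float) / 10.0)
            names.append("age_per_10y")
            continue
        series = clinical[cov].astype(str)
        if cov == "grade" and merge_grades_1:
            series = series.replace({"1b": "1a/1b", "1a": "1a/1b"})
        levels = sorted(series.unique())
        for lev in levels[1:]:
            col = (series == lev).to_numpy(dtype=float)
            if 0 < col.sum() < len(col):
                cols.append(col)
                names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    keep = [i for i in range(X.shape[1]) if i == 0 or X[:, i].std() > 0]
    return X[:, keep], [names[i] for i in keep]


def _burden_predictor(counts: np.ndarray, pseudo_count: float = 1.0) -> np.ndarray:
    return np.log2(np.asarray(counts, dtype=float) + pseudo_count)


def burden_association(
    summaries: pd.DataFrame,
    clinical: pd.DataFrame,
    n_probes: int,
    scope: str = "cohort",
    adjusted: bool = False,
    burden: str = "altered",
    include_cnloh: bool = False,
    pseudo_count: float = 1.0,
) -> AssociationResult:
    """Logistic model of recurrence on instability burden.

    ``scope`` is "cohort" or a tumor type. ``burden`` selects the probe
    class counted ("altered", "gained", "deleted", "loh");
    ``include_cnloh`` adds copy-neutral LOH probes to the altered count.
    The adjusted model adds tumor type (whole cohort only), grade (1a+1b
    merged within a type), age and sex; the LRT compares the models with
    and without the burden term.
    """
    df = clinical.join(summaries, how="inner")
    flags: list[str] = []
    if scope != "cohort":
        df = df[df["tumor_type"] == scope]
        if len(df) < 10:
            flags.append("low_power")
    y = df["recurrence"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"scope {scope!r} lacks both outcome classes")
    frac_col = {"altered": "altered_frac", "gained": "gained_frac",
                "deleted": "deleted_frac", "loh": "loh_frac"}[burden]
    if burden == "altered" and include_cnloh:
        frac_col = "altered_with_loh_frac"
    counts = df[frac_col].to_numpy(dtype=float) * n_probes
    x = _burden_predictor(counts, pseudo_count)

    if adjusted:
        covs = ["grade", "age", "sex"] + (["tumor_type"] if scope == "cohort" else [])
        X0, names0 = build_design(df, covs, merge_grades_1=(scope != "cohort"))
    else:
        X0, names0 = np.ones((len(df), 1)), ["intercept"]
    name = f"log2_{burden}_probes"
    if np.std(x) == 0:
        return AssociationResult(
            predictor=name, odds_ratio=1.0, ci_low=np.nan, ci_high=np.nan,
            lrt_stat=0.0, lrt_df=1, p_value=1.0,
            covariates=names0[1:], flags=flags + ["constant_burden"],
        )
    X1 = np.column_stack([X0, x])
    full = fit_logistic(y, X1, columns=names0 + [name])
    red = fit_logistic(y, X0, columns=names0)
    stat, ddf, p = likelihood_ratio_test(full, red)
    lo, hi = full.wald_ci(name)
    if full.separated:
        flags.append("separation")
    return AssociationResult(
        predictor=name, odds_ratio=full.odds_ratio(name),
        ci_low=float(np.exp(min(lo, 700.0))), ci_high=float(np.exp(min(hi, 700.0))),
        lrt_stat=stat, lrt_df=ddf, p_value=p,
        covariates=names0[1:], flags=flags,
    )


def _scan_status_matrix(
    status: pd.DataFrame,
    clinical: pd.DataFrame,
    scope: str,
    adjusted: bool,
    covariates: list[str],
    adjust_method: str,
    binarize: bool,
    merge_grades_1: bool,
) -> pd.DataFrame:
    """Shared engine of the per-probe and per-gene scans.

    ``status`` is features x samples with values in {-1, 0, +1}. Identical
    status rows (features inside one CNV region) are fit once and their
    result broadcast, which keeps genome-wide scans tractable. Multiple-
    testing adjustment covers the actually-tested (non-constant) features
    only; skipped features carry a flag instead of a p-value.
    """
    df = clinical.copy()
    if scope != "cohort":
        df = df[df["tumor_type"] == scope]
    samples = [s for s in status.columns if s in df.index]
    df = df.loc[samples]
    y = df["recurrence"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"scope {scope!r} lacks both outcome classes")
    if adjusted:
        X0, names0 = build_design(df, covariates, merge_grades_1=merge_grades_1)
    else:
        X0, names0 = np.ones((len(df), 1)), ["intercept"]
    red = fit_logistic(y, X0, columns=names0)

    vals = status[samples].to_numpy()
    if binarize:
        vals = (vals != 0).astype(np.int8)
    uniq, inverse = np.unique(vals, axis=0, return_inverse=True)
    results: list[dict] = []
    for u in range(len(uniq)):
        row = uniq[u]
        rec: dict = {"or_gain": np.nan, "or_loss": np.nan, "or_altered": np.nan,
                     "lrt_stat": np.nan, "lrt_df": 0, "p_value": np.nan, "flag": ""}
        levels = np.unique(row)
        if len(levels) < 2:
            rec["flag"] = "constant"
        else:
            cols, cnames = [], []
            if binarize:
                cols.append((row == 1).astype(float))
                cnames.append("altered")
            else:
                for lev, nm in ((1, "gain"), (-1, "loss")):
                    if (row == lev).any() and not (row == lev).all():
                        cols.append((row == lev).astype(float))
                        cnames.append(nm)
            if not cols:
                rec["flag"] = "constant"
            else:
                X1 = np.column_stack([X0] + cols)
                try:
                    full = fit_logistic(y, X1, columns=names0 + cnames)
                    stat, ddf, p = likelihood_ratio_test(full, red)
                    rec.update(lrt_stat=stat, lrt_df=ddf, p_value=p)
                    for nm in cnames:
                        rec[f"or_{nm}"] = full.odds_ratio(nm)
                    if full.separated:
                        rec["flag"] = "separation"
                except (ValueError, np.linalg.LinAlgError) as exc:
                    rec["flag"] = f"fit_error:{type(exc).__name__}"
        results.append(rec)

    out = pd.DataFrame([results[i] for i in inverse], index=status.index)
    tested = out["p_value"].notna()
    out["adjusted_p"] = np.nan
    if tested.any():
        # each feature is its own test: adjust over all tested features,
        # duplicated patterns included (m = number of tested features)
        out.loc[tested, "adjusted_p"] = adjust_pvalues(
            out.loc[tested, "p_value"].to_numpy(), method=adjust_method)
    out["adjustment"] = adjust_method
    return out


def per_probe_scan(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    scope: str = "cohort",
    adjusted: bool = False,
    adjust_method: str = "BY",
) -> pd.DataFrame:
    """Genome-wide per-probe recurrence scan (probe status categorical, ref normal).

    ``matrix`` is samples x probes; returns a probes-indexed table with
    per-level odds ratios, LRT statistic/df, raw and BY-adjusted p-values
    and flags. Probes observed in only two of the three states are fit
    with one degree of freedom.
    """
    covs = ["grade", "age", "sex"] + (["tumor_type"] if scope == "cohort" else [])
    return _scan_status_matrix(
        matrix.T, clinical, scope, adjusted, covs, adjust_method,
        binarize=False, merge_grades_1=(scope != "cohort"),
    )


class BEDParseError(ValueError):
    pass


def read_gene_bed(path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open) into 1-based inclusive."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise BEDParseError(f"line {ln}: expected >= 4 BED columns")
            try:
                chrom = int(parts[0].removeprefix("chr"))
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BEDParseError(f"line {ln}: {exc}") from exc
            if end0 <= start0:
                raise BEDParseError(f"line {ln}: end <= start")
            rows.append({"gene": parts[3], "chrom": chrom,
                         "start": start0 + 1, "end": end0})
    return (pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
            .sort_values(["chrom", "start"], kind="stable").reset_index(drop=True))


def map_genes_to_status(
    segments: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample alteration status from called segments.

    A gene takes the state of any overlapping altered segment; when one
    sample overlaps the gene with both gained and lost segments, the state
    covering the larger fraction of the gene wins and exact ties are
    flagged ambiguous (resolved to loss for determinism). Returns
    (status frame genes x samples, boolean ambiguity frame).
    """
    if samples is None:
        samples = list(dict.fromkeys(segments["sample_id"]))
    genes = gene_annotation.reset_index(drop=True)
    status = np.zeros((len(genes), len(samples)), dtype=np.int8)
    ambiguous = np.zeros_like(status, dtype=bool)
    col_of = {s: j for j, s in enumerate(samples)}
    g_by_chrom = {c: sub for c, sub in genes.groupby("chrom")}
    alt = segments[segments["state"] != "neutral"]
    overlap_gain = np.zeros((len(genes), len(samples)), dtype=np.int64)
    overlap_loss = np.zeros_like(overlap_gain)
    for rec in alt.itertuples(index=False):
        j = col_of.get(rec.sample_id)
        if j is None:
            continue
        sub = g_by_chrom.get(rec.chrom)
        if sub is None:
            continue
        hit = sub[(sub["start"] <= rec.end) & (sub["end"] >= rec.start)]
        if hit.empty:
            continue
        ov = (np.minimum(hit["end"].to_numpy(), rec.end)
              - np.maximum(hit["start"].to_numpy(), rec.start) + 1)
        tgt = overlap_gain if rec.state == "gain" else overlap_loss
        tgt[hit.index.to_numpy(), j] += ov
    status[overlap_gain > overlap_loss] = 1
    status[overlap_loss > overlap_gain] = -1
    tie = (overlap_gain == overlap_loss) & (overlap_gain > 0)
    status[tie] = -1
    ambiguous[tie] = True
    idx = pd.Index(genes["gene"], name="gene")
    return (pd.DataFrame(status, index=idx, columns=samples),
            pd.DataFrame(ambiguous, index=idx, columns=samples))


def per_gene_scan(
    gene_status: pd.DataFrame,
    clinical: pd.DataFrame,
    scope: str = "lactotroph",
    adjusted: bool = True,
    adjust_method: str = "BH",
) -> pd.DataFrame:
    """Per-gene recurrence scan on binarized (altered vs not) gene status.

    The adjusted model uses age, sex and grade (1a+1b merged); tumor type
    is omitted because the scan runs within one lineage.
    """
    return _scan_status_matrix(
        gene_status, clinical, scope, adjusted,
        ["grade", "age", "sex"], adjust_method,
        binarize=True, merge_grades_1=True,
    )
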