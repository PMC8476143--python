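"""Cross-species intron association statistics.

Covers the comparative statistics downstream of the reconstruction:
pairwise intron-retention concordance against the independence
expectation, Bayesian binomial intervals, Fisher tests of
selection/duplication flags against intron status, the GO relative
intron-abundance score, the bit-score threshold via a lognormal+normal
mixture fitted by EM, and RPKM / translation-efficiency expression
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairConcordance",
    "pair_concordance",
    "bayes_binom_ci",
    "flag_enrichment",
    "go_intron_score",
    "MixtureFit",
    "mixture_threshold",
    "rpkm",
    "translation_efficiency",
    "expression_compare",
]

ORTHOLOG_COLUMNS = ["set_id", "species", "has_intron", "selected", "duplicated",
                    "go_terms"]


def read_ortholog_table(path) -> pd.DataFrame:
    """Read the ortholog membership TSV (one row per set x species)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("set_id", "species", "has_intron") if c not in df.columns]
    if missing:
        raise ValueError(f"ortholog table missing columns {missing}")
    for col in ("has_intron", "selected", "duplicated"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


@dataclass
class PairConcordance:
    """Concordance of intron retention between two species."""

    species_a: str
    species_b: str
    n: int
    observed_both: int
    expected_both: float
    ratio: float
    chi2: float
    p: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    table: np.ndarray = field(default=None, repr=False)


def pair_concordance(
    orthologs: pd.DataFrame,
    species_a: str,
    species_b: str,
    correction: bool = False,
    draws: int = 1000,
    seed: int = 0,
) -> PairConcordance:
    """Observed vs expected count of ortholog pairs with introns in both.

    Over the ortholog sets containing both species, the expectation under
    independent retention is n * pA * pB with pA, pB the marginal intron
    fractions.  The chi-square test is the 2x2 independence test (no
    continuity correction by default).  The 95% interval comes from
    Jeffreys-posterior sampling of the both-intron proportion, transformed
    by n / expected onto the ratio scale.
    """
    wide = (
        orthologs[orthologs["species"].isin([species_a, species_b])]
        .pivot_table(index="set_id", columns="species", values="has_intron",
                     aggfunc="first")
        .dropna()
    )
    if len(wide) == 0:
        raise ValueError("no ortholog set contains both species")
    a = wide[species_a].astype(bool).to_numpy()
    b = wide[species_b].astype(bool).to_numpy()
    n = len(wide)
    observed = int(np.sum(a & b))
    pa, pb = a.mean(), b.mean()
    expected = n * pa * pb
    table = np.array(
        [
            [np.sum(a & b), np.sum(a & ~b)],
            [np.sum(~a & b), np.sum(~a & ~b)],
        ]
    )
    if expected > 0:
        ratio = observed / expected
    else:
        ratio = float("nan")
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    else:
        chi2, p = 0.0, 1.0
    lo, hi = bayes_binom_ci(observed, n, draws=draws, seed=seed)
    scale = n / expected if expected > 0 else float("nan")
    return PairConcordance(
        species_a=species_a, species_b=species_b, n=n,
        observed_both=observed, expected_both=float(expected),
        ratio=float(ratio), chi2=float(chi2), p=float(p),
        ci_low=float(lo * scale), ci_high=float(hi * scale), table=table,
    )


def bayes_binom_ci(
    successes: int, n: int, draws: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """95% Bayesian binomial interval by Jeffreys-posterior sampling.

    Samples ``draws`` values from Beta(successes + 1/2, n - successes +
    1/2) and returns the empirical 2.5/97.5 percentiles.  Deterministic
    under ``seed``.
    """
    if n < 1 or not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n with n >= 1")
    rng = np.random.default_rng(seed)
    sample = rng.beta(successes + 0.5, n - successes + 0.5, size=draws)
    lo, hi = np.percentile(sample, [2.5, 97.5])
    return float(lo), float(hi)


def flag_enrichment(
    orthologs: pd.DataFrame,
    species: str,
    flag: str,
    sidedness: str | None = None,
) -> dict:
    """Fisher exact test of intron status against a gene flag.

    ``flag`` is "selected" (positive selection; one-sided by default,
    alternative "less": intron-containing genes are hypothesized to be
    depleted in recent positive selection) or "duplicated" (two-sided by
    default).  A zero margin yields p = 1 with the odds ratio flagged
    undefined.
    """
    if flag not in ("selected", "duplicated"):
        raise ValueError("flag must be 'selected' or 'duplicated'")
    sub = orthologs[orthologs["species"] == species]
    if len(sub) == 0:
        raise ValueError(f"no rows for species {species!r}")
    intron = sub["has_intron"].to_numpy(dtype=bool)
    flagged = sub[flag].to_numpy(dtype=bool)
    table = np.array(
        [
            [np.sum(intron & flagged), np.sum(intron & ~flagged)],
            [np.sum(~intron & flagged), np.sum(~intron & ~flagged)],
        ]
    )
    if sidedness is None:
        sidedness = "one" if flag == "selected" else "two"
    alternative = {"one": "less", "two": "two-sided"}.get(sidedness, sidedness)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return {"table": table, "odds_ratio": float("nan"), "p": 1.0,
                "alternative": alternative, "defined": False}
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return {"table": table, "odds_ratio": float(odds), "p": float(p),
            "alternative": alternative, "defined": True}


def go_intron_score(xi: int, sx: int, ci: int, sc: int) -> float:
    """Relative intron abundance of a GO term in one species (bits).

        score = log2((xi + 1) / sx) - log2(ci / sc)

    xi: introns in the term's genes; sx: genes in the term; ci: the
    species' total introns within the ortholog sets; sc: number of
    ortholog sets.
    """
    if sx < 1 or sc < 1:
        raise ValueError("sx and sc must be >= 1")
    if ci < 1:
        raise ValueError("score undefined for ci = 0")
    return float(np.log2((xi + 1) / sx) - np.log2(ci / sc))


# -- bit-score threshold by lognormal + normal mixture EM ------------------


@dataclass
class MixtureFit:
    """Two-component (lognormal + normal) mixture fitted by EM."""

    weight_lognormal: float
    mu_log: float      # mean of log scores, lognormal component
    sigma_log: float
    mu_norm: float
    sigma_norm: float
    loglik: float
    n_iterations: int
    converged: bool
    loglik_path: np.ndarray = field(default=None, repr=False)

    def component_pdfs(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f1 = stats.lognorm.pdf(x, s=self.sigma_log, scale=np.exp(self.mu_log))
        f2 = stats.norm.pdf(x, loc=self.mu_norm, scale=self.sigma_norm)
        return f1, f2

    def mixture_loglik_at(self, x: np.ndarray) -> float:
        f1, f2 = self.component_pdfs(x)
        w = self.weight_lognormal
        return float(np.sum(np.log(np.maximum(w * f1 + (1 - w) * f2, 1e-300))))


def _em_fit(x: np.ndarray, init_split: float, max_iter: int, tol: float) -> MixtureFit:
    q = np.quantile(x, init_split)
    low, high = x[x <= q], x[x > q]
    if len(low) < 2 or len(high) < 2:
        low, high = x[: len(x) // 2], x[len(x) // 2:]
    w = len(low) / len(x)
    mu_l, sd_l = np.log(low).mean(), max(np.log(low).std(), 1e-3)
    mu_n, sd_n = high.mean(), max(high.std(), 1e-3)
    fit = MixtureFit(w, mu_l, sd_l, mu_n, sd_n, -np.inf, 0, False)
    path = []
    for it in range(1, max_iter + 1):
        f1, f2 = fit.component_pdfs(x)
        num1 = fit.weight_lognormal * f1
        num2 = (1 - fit.weight_lognormal) * f2
        total = np.maximum(num1 + num2, 1e-300)
        r1 = num1 / total
        ll = float(np.sum(np.log(total)))
        path.append(ll)
        w1 = r1.sum()
        if w1 < 1e-9 or w1 > len(x) - 1e-9:
            break
        logx = np.log(x)
        mu_l = np.sum(r1 * logx) / w1
        sd_l = max(np.sqrt(np.sum(r1 * (logx - mu_l) ** 2) / w1), 1e-4)
        r2 = 1 - r1
        w2 = r2.sum()
        mu_n = np.sum(r2 * x) / w2
        sd_n = max(np.sqrt(np.sum(r2 * (x - mu_n) ** 2) / w2), 1e-4)
        new = MixtureFit(w1 / len(x), mu_l, sd_l, mu_n, sd_n, ll, it, False)
        if abs(ll - fit.loglik) < tol:
            new.converged = True
            fit = new
            break
        fit = new
    fit.loglik_path = np.asarray(path)
    return fit


def mixture_threshold(
    scores, seed: int = 0, draws: int = 10000,
    max_iter: int = 500, tol: float = 1e-6,
) -> dict:
    """Bit-score cutoff from a bimodal lognormal + normal mixture.

    The mixture is fitted by EM (multi-start over initial quantile
    splits); the threshold is the crossing point of the two weighted
    component densities between the component modes, located on a grid of
    Monte-Carlo draws from the fitted mixture.  A degenerate fit (either
    weight below 1e-3) is flagged with an undefined threshold.
    """
    x = np.asarray(scores, dtype=float)
    if len(x) < 50:
        raise ValueError("need >= 50 scores")
    if np.any(x <= 0):
        raise ValueError("scores must be > 0 (lognormal support)")
    best = None
    for split in (0.3, 0.5, 0.7):
        fit = _em_fit(x, split, max_iter, tol)
        if best is None or fit.loglik > best.loglik:
            best = fit
    w = best.weight_lognormal
    if min(w, 1 - w) < 1e-3:
        return {"fit": best, "threshold": float("nan"), "degenerate": True}

    rng = np.random.default_rng(seed)
    n1 = int(round(draws * w))
    sample = np.concatenate(
        [
            rng.lognormal(best.mu_log, best.sigma_log, size=n1),
            rng.normal(best.mu_norm, best.sigma_norm, size=draws - n1),
        ]
    )
    mode_l = np.exp(best.mu_log - best.sigma_log**2)
    mode_n = best.mu_norm
    lo, hi = sorted((mode_l, mode_n))
    grid = np.sort(sample[(sample > lo) & (sample < hi)])
    if len(grid) == 0:
        return {"fit": best, "threshold": float("nan"), "degenerate": True}
    f1, f2 = best.component_pdfs(grid)
    diff = w * f1 - (1 - w) * f2
    sign_change = np.nonzero(np.diff(np.sign(diff)))[0]
    if len(sign_change) > 0:
        i = sign_change[0]
        threshold = 0.5 * (grid[i] + grid[i + 1])
    else:
        threshold = grid[np.argmin(np.abs(diff))]
    return {"fit": best, "threshold": float(threshold), "degenerate": False}


# -- expression metrics ----------------------------------------------------


def rpkm(m: float, l: float, n: float) -> float:
    """Reads per kilobase per million mapped reads: 1e9 * m / (n * l)."""
    if l <= 0 or n <= 0:
        raise ValueError("gene length and library size must be > 0")
    if m < 0:
        raise ValueError("read count must be >= 0")
    return 1e9 * m / (n * l)


def translation_efficiency(p: float, q: float, m: float, n: float) -> float:
    """Footprint density over mRNA density: (p / q) * (n / m).

    Undefined for m = 0 (returns NaN; such genes are excluded from
    comparisons).
    """
    if q <= 0 or n <= 0:
        raise ValueError("library sizes must be > 0")
    if m == 0:
        return float("nan")
    return (p / q) * (n / m)


def expression_compare(
    records: pd.DataFrame, pseudocount: float = 1.0
) -> dict:
    """Group-wise expression statistics and Welch tests.

    ``records`` needs gene_id, length, has_intron, go_class, rna_count,
    fp_count.  Genes are grouped into four classes by (intron status) x
    (go_class == "translation"); RPKM and TE are computed from the table's
    own library sizes, log2(x + pseudocount)-transformed, and
    intron-containing vs intronless genes are compared with Welch's
    t-test within each GO class.  Genes with zero RNA count have
    undefined TE and are excluded from the TE comparison.
    """
    df = records.copy()
    n_lib = float(df["rna_count"].sum())
    q_lib = float(df["fp_count"].sum())
    if n_lib <= 0 or q_lib <= 0:
        raise ValueError("empty libraries")
    df["rpkm"] = 1e9 * df["rna_count"] / (n_lib * df["length"])
    with np.errstate(divide="ignore", invalid="ignore"):
        df["te"] = np.where(
            df["rna_count"] > 0,
            (df["fp_count"] / q_lib) * (n_lib / df["rna_count"]),
            np.nan,
        )
    df["group"] = np.where(df["has_intron"], "+", "-") + np.where(
        df["go_class"] == "translation", "+", "-"
    )
    group_stats = (
        df.groupby("group")
        .agg(n=("gene_id", "size"), mean_rpkm=("rpkm", "mean"),
             median_rpkm=("rpkm", "median"), mean_te=("te", "mean"),
             median_te=("te", "median"))
        .reset_index()
    )
    tests = []
    for go_label, go_plus in (("translation", True), ("other", False)):
        sel = (df["go_class"] == "translation") == go_plus
        for metric in ("rpkm", "te"):
            x = df.loc[sel & df["has_intron"], metric].dropna()
            y = df.loc[sel & ~df["has_intron"], metric].dropna()
            if len(x) < 2 or len(y) < 2:
                tests.append({"go_class": go_label, "metric": metric,
                              "t": np.nan, "p": np.nan, "skipped": True,
                              "n_intron": len(x), "n_intronless": len(y)})
                continue
            lx = np.log2(x + pseudocount)
            ly = np.log2(y + pseudocount)
            if np.var(lx) == 0 and np.var(ly) == 0:
                t, p = (0.0, 1.0) if lx.mean() == ly.mean() else (np.inf, 0.0)
            else:
                t, p = stats.ttest_ind(lx, ly, equal_var=False)
            tests.append({"go_class": go_label, "metric": metric,
                          "t": float(t), "p": float(p), "skipped": False,
                          "n_intron": len(x), "n_intronless": len(y)})
    return {"records": df, "group_stats": group_stats,
            "tests": pd.DataFrame(tests)}
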