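"""Perception-based severity reference: the Davidson tie-extension of the
Bradley–Terry model fitted by MCMC, rank concordance (Kendall's W), rank
correlation (Kendall's tau-b) and index benchmarking.

The Davidson model assigns each subject a positive ability π_i (λ_i = log
π_i) and a global tie propensity ν ≥ 0; for a comparison of i and j,

    P(i wins) = π_i / D,   P(j wins) = π_j / D,
    P(tie)    = ν √(π_i π_j) / D,     D = π_i + π_j + ν √(π_i π_j).

The likelihood is invariant to a common rescaling of all π, so λ carries a
sum-to-zero identifiability constraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
from scipy import stats


class RankingError(ValueError):
    """Invalid judgments or ranking parameters."""


OUTCOMES = ("i", "j", "tie")


@dataclass
class PairwiseJudgments:
    """Long-form table of pairwise severity comparisons.

    One row per (rater, pair): ``outcome`` is ``"i"`` if subject_i was judged
    more severe, ``"j"`` for subject_j, ``"tie"`` for comparable severity.
    """

    table: pd.DataFrame
    roster: list[str]

    def __post_init__(self) -> None:
        required = {"rater_id", "subject_i", "subject_j", "outcome"}
        if not required.issubset(self.table.columns):
            raise RankingError(f"judgment table needs columns {sorted(required)}")
        if (self.table["subject_i"] == self.table["subject_j"]).any():
            raise RankingError("self-comparisons are not allowed")
        bad = set(self.table["outcome"]) - set(OUTCOMES)
        if bad:
            raise RankingError(f"unknown outcomes {sorted(bad)}")
        known = set(self.roster)
        used = set(self.table["subject_i"]) | set(self.table["subject_j"])
        if not used.issubset(known):
            raise RankingError("judgments mention subjects outside the roster")

    @property
    def n_judgments(self) -> int:
        return len(self.table)

    def connected_components(self) -> list[set[str]]:
        """Components of the comparison graph over the roster."""
        parent = {s: s for s in self.roster}

        def find(a: str) -> str:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for _, row in self.table.iterrows():
            ra, rb = find(row["subject_i"]), find(row["subject_j"])
            if ra != rb:
                parent[ra] = rb
        groups: dict[str, set[str]] = {}
        for s in self.roster:
            groups.setdefault(find(s), set()).add(s)
        return list(groups.values())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, roster: list[str] | None = None) -> "PairwiseJudgments":
        table = pd.read_csv(path, dtype={"subject_i": str, "subject_j": str})
        if roster is None:
            roster = sorted(set(table["subject_i"]) | set(table["subject_j"]))
        return cls(table=table, roster=list(roster))


def davidson_probabilities(
    pi_i: float | np.ndarray, pi_j: float | np.ndarray, nu: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(P_i_wins, P_j_wins, P_tie) under the Davidson model."""
    pi_i = np.asarray(pi_i, dtype=float)
    pi_j = np.asarray(pi_j, dtype=float)
    if np.any(pi_i <= 0) or np.any(pi_j <= 0):
        raise RankingError("abilities must be positive")
    if nu < 0:
        raise RankingError("tie parameter must be non-negative")
    tie_term = nu * np.sqrt(pi_i * pi_j)
    denom = pi_i + pi_j + tie_term
    return pi_i / denom, pi_j / denom, tie_term / denom


@dataclass
class DavidsonModel:
    """Posterior draws for the Davidson–Bradley–Terry model."""

    roster: list[str]
    lambda_draws: np.ndarray  # draws × n subjects, each row sums to zero
    log_nu_draws: np.ndarray
    prior_sd: float
    acceptance_fraction: float

    @property
    def lambda_mean(self) -> np.ndarray:
        return self.lambda_draws.mean(axis=0)

    @property
    def nu_mean(self) -> float:
        return float(np.exp(self.log_nu_draws).mean())


@dataclass
class RankingResult:
    """Posterior severity summaries and the implied ranking."""

    roster: list[str]
    posterior_mean: np.ndarray
    posterior_median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    ranking: list[str]  # most severe first
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(-self.posterior_mean)
        rank = np.empty(len(self.roster), dtype=int)
        rank[order] = np.arange(1, len(self.roster) + 1)
        return pd.DataFrame(
            {
                "subject_id": self.roster,
                "posterior_mean": self.posterior_mean,
                "posterior_median": self.posterior_median,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "rank": rank,
            }
        )


def _log_posterior(
    params: np.ndarray,
    idx_i: np.ndarray,
    idx_j: np.ndarray,
    outcome_code: np.ndarray,
    n_subjects: int,
    prior_sd: float,
) -> float:
    lam = params[:n_subjects]
    log_nu = params[n_subjects]
    if abs(log_nu) > 20:
        return -np.inf
    lam_c = lam - lam.mean()  # likelihood depends on centred λ only
    li, lj = lam_c[idx_i], lam_c[idx_j]
    # log-scale Davidson terms: log π_i = λ_i, log tie term = log ν + (λ_i+λ_j)/2
    a = np.stack([li, lj, log_nu + 0.5 * (li + lj)], axis=1)
    log_denom = np.logaddexp.reduce(a, axis=1)
    loglik = np.sum(a[np.arange(len(idx_i)), outcome_code] - log_denom)
    log_prior = -0.5 * np.sum(lam**2) / prior_sd**2 - 0.5 * log_nu**2
    return loglik + log_prior


def fit_davidson_bt(
    judgments: PairwiseJudgments,
    prior_sd: float = 2.0,
    n_walkers: int = 64,
    n_steps: int = 1500,
    burn_in: int = 500,
    thin: int = 2,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[DavidsonModel, RankingResult]:
    """Fit the Bayesian Davidson–Bradley–Terry model by affine-invariant
    ensemble MCMC and return posterior summaries plus the implied ranking.

    Priors: λ_i ~ Normal(0, prior_sd²) with the sum-to-zero constraint
    enforced on every draw (the likelihood is shift-invariant, so centring
    draws is exact); log ν ~ Normal(0, 1).
    """
    if judgments.n_judgments == 0:
        raise RankingError("no judgments to fit")
    roster = list(judgments.roster)
    used = set(judgments.table["subject_i"]) | set(judgments.table["subject_j"])
    missing = set(roster) - used
    if missing:
        raise RankingError(f"subjects never judged: {sorted(missing)}")
    components = judgments.connected_components()
    if len(components) > 1:
        warnings.warn(
            f"comparison graph has {len(components)} disconnected components: "
            f"{[sorted(c) for c in components]}; relative severities across "
            "components are informed only by the prior",
            stacklevel=2,
        )
    index = {s: k for k, s in enumerate(roster)}
    idx_i = judgments.table["subject_i"].map(index).to_numpy()
    idx_j = judgments.table["subject_j"].map(index).to_numpy()
    outcome_code = judgments.table["outcome"].map(
        {"i": 0, "j": 1, "tie": 2}
    ).to_numpy()
    n = len(roster)
    ndim = n + 1

    rng = np.random.default_rng(seed)
    # crude data-driven start: net win fraction per subject
    wins = np.bincount(idx_i[outcome_code == 0], minlength=n) + np.bincount(
        idx_j[outcome_code == 1], minlength=n
    )
    games = np.bincount(idx_i, minlength=n) + np.bincount(idx_j, minlength=n)
    start = (wins + 0.5) / (games + 1.0)
    start = np.log(start / (1 - start))
    start -= start.mean()
    p0 = start[None, :] + 0.1 * rng.standard_normal((n_walkers, n))
    p0 = np.concatenate([p0, 0.1 * rng.standard_normal((n_walkers, 1))], axis=1)

    sampler = emcee.EnsembleSampler(
        n_walkers,
        ndim,
        _log_posterior,
        args=(idx_i, idx_j, outcome_code, n, prior_sd),
    )
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=burn_in, thin=thin, flat=True)
    lam_draws = chain[:, :n]
    lam_draws = lam_draws - lam_draws.mean(axis=1, keepdims=True)
    log_nu_draws = chain[:, n]
    model = DavidsonModel(
        roster=roster,
        lambda_draws=lam_draws,
        log_nu_draws=log_nu_draws,
        prior_sd=prior_sd,
        acceptance_fraction=float(sampler.acceptance_fraction.mean()),
    )
    alpha = (1 - ci_level) / 2
    mean = lam_draws.mean(axis=0)
    order = np.argsort(-mean)
    result = RankingResult(
        roster=roster,
        posterior_mean=mean,
        posterior_median=np.median(lam_draws, axis=0),
        ci_low=np.quantile(lam_draws, alpha, axis=0),
        ci_high=np.quantile(lam_draws, 1 - alpha, axis=0),
        ranking=[roster[k] for k in order],
        diagnostics={
            "acceptance_fraction": model.acceptance_fraction,
            "n_draws": int(lam_draws.shape[0]),
            "n_components": len(components),
        },
    )
    return model, result


def kendalls_w(
    rank_matrix: np.ndarray,
    permutation_p: bool = False,
    n_permutations: int = 2000,
    seed: int = 0,
) -> dict:
    """Kendall's coefficient of concordance for m raters × n subjects.

    Rows are converted to mid-ranks; the tie-corrected statistic is

        W = 12 S / (m² (n³ − n) − m ΣT),   T = Σ (t³ − t) over tie groups,

    with S the sum of squared deviations of subject rank sums from their
    mean.  p comes from the χ² approximation χ² = m (n − 1) W with n − 1
    degrees of freedom, optionally also from a seeded permutation test
    (independently re-ranking each rater).
    """
    scores = np.asarray(rank_matrix, dtype=float)
    if scores.ndim != 2:
        raise RankingError("rank matrix must be 2-D (raters × subjects)")
    m, n = scores.shape
    if m < 2 or n < 2:
        raise RankingError("need at least two raters and two subjects")
    if not np.isfinite(scores).all():
        raise RankingError("ranks must be finite")
    ranks = np.vstack([stats.rankdata(row) for row in scores])

    def _w(ranks_: np.ndarray) -> float:
        rank_sums = ranks_.sum(axis=0)
        s = np.sum((rank_sums - rank_sums.mean()) ** 2)
        tie_corr = 0.0
        for row in ranks_:
            _, counts = np.unique(row, return_counts=True)
            tie_corr += np.sum(counts**3 - counts)
        denom = m**2 * (n**3 - n) - m * tie_corr
        if denom <= 0:
            return 1.0  # every rater ties everything; degenerate full agreement
        return float(12 * s / denom)

    w = _w(ranks)
    chi2 = m * (n - 1) * w
    p_chi2 = float(stats.chi2.sf(chi2, n - 1))
    out = {"W": w, "chi2": chi2, "p": p_chi2, "df": n - 1}
    if permutation_p:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = np.vstack([rng.permutation(row) for row in ranks])
            if _w(perm) >= w - 1e-12:
                count += 1
        out["p_permutation"] = (count + 1) / (n_permutations + 1)
    return out


def kendalls_tau(x: np.ndarray, y: np.ndarray) -> dict:
    """Kendall's tau-b with tie correction.

    Exact p-value by enumeration for n ≤ 8 without ties, otherwise the
    normal approximation.  Constant input makes tau undefined; reported as
    NaN rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise RankingError("inputs must be equal-length 1-D arrays, n ≥ 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"tau": float("nan"), "p": float("nan")}
    n = len(x)
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    method = "exact" if (n <= 8 and not has_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return {"tau": float(res.statistic), "p": float(res.pvalue)}


def rankings_from_judgments(judgments: PairwiseJudgments) -> np.ndarray:
    """Per-rater severity scores (win − loss counts) over the roster, as an
    m × n matrix suitable for :func:`kendalls_w`."""
    roster = judgments.roster
    index = {s: k for k, s in enumerate(roster)}
    raters = sorted(judgments.table["rater_id"].unique())
    scores = np.zeros((len(raters), len(roster)))
    for r, rater in enumerate(raters):
        sub = judgments.table[judgments.table["rater_id"] == rater]
        for _, row in sub.iterrows():
            if row["outcome"] == "i":
                scores[r, index[row["subject_i"]]] += 1
                scores[r, index[row["subject_j"]]] -= 1
            elif row["outcome"] == "j":
                scores[r, index[row["subject_j"]]] += 1
                scores[r, index[row["subject_i"]]] -= 1
    return scores


def benchmark_indices(
    severity_table: pd.DataFrame,
    ranking: RankingResult,
    method: str = "kendall",
    index_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Correlate every severity index with the expert latent severity.

    Returns one row per index with the correlation coefficient and p-value,
    sorted by absolute correlation (strongest agreement first).
    """
    if method not in ("kendall", "spearman"):
        raise RankingError("method must be 'kendall' or 'spearman'")
    if "subject_id" not in severity_table.columns:
        raise RankingError("severity table needs a subject_id column")
    table = severity_table.set_index("subject_id")
    common = [s for s in ranking.roster if s in table.index]
    if len(common) < 3:
        raise RankingError("need at least three subjects common to both inputs")
    latent = pd.Series(ranking.posterior_mean, index=ranking.roster).loc[common]
    if index_columns is None:
        index_columns = [
            c for c in table.columns
            if pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for col in index_columns:
        vals = table.loc[common, col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() < 3:
            rows.append({"index": col, "correlation": np.nan, "p": np.nan,
                         "n": int(ok.sum())})
            continue
        if method == "kendall":
            res = kendalls_tau(vals[ok], latent.to_numpy()[ok])
            corr, p = res["tau"], res["p"]
        else:
            r = stats.spearmanr(vals[ok], latent.to_numpy()[ok])
            corr, p = float(r.statistic), float(r.pvalue)
        rows.append({"index": col, "correlation": corr, "p": p, "n": int(ok.sum())})
    out = pd.DataFrame(rows)
    return out.reindex(
        out["correlation"].abs().sort_values(ascending=False, na_position="last").index
    ).reset_index(drop=True)


def pairwise_score_correlations(
    severity_table: pd.DataFrame, columns: list[str], method: str = "spearman"
) -> pd.DataFrame:
    """Pairwise correlations among shape scores and classical indices
    (scatter-matrix style summary over the subject roster)."""
    table = severity_table[columns].astype(float)
    return table.corr(method=method)
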