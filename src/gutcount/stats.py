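"""Group-comparison layer: mean±s.e.m., omnibus and post-hoc tests.

Parametric route: one-way ANOVA with Tukey's HSD pairwise test.
Non-parametric route: Kruskal-Wallis with Dunn's pairwise test
(tie-corrected z statistics, Holm adjustment by default, Bonferroni
optional).  "auto" picks the parametric route unless any group fails a
Shapiro-Wilk normality check at alpha = 0.05.

Significance stars: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

STAR_CUTPOINTS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars(p: float) -> str:
    """Significance stars for an (adjusted) p-value; 'ns' when p >= 0.05."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of [0, 1]: {p}")
    for cut, symbol in STAR_CUTPOINTS:
        if p < cut:
            return symbol
    return "ns"


def mean_sem(values) -> tuple[float, float | None]:
    """Arithmetic mean and standard error (sample SD / sqrt(n)).

    sem is None for a single value; an empty input is an error.
    """
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("mean_sem requires at least one finite value")
    mean = float(x.mean())
    if x.size < 2:
        return mean, None
    return mean, float(x.std(ddof=1) / math.sqrt(x.size))


@dataclass
class GroupComparison:
    metric: str
    mode: str  # "parametric" | "nonparametric"
    group_names: list[str]
    group_n: dict[str, int]
    group_mean: dict[str, float]
    group_sem: dict[str, float | None]
    omnibus: dict[str, float]  # {anova_F, anova_p} or {kruskal_H, kruskal_p}
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    n_dropped: dict[str, int] = field(default_factory=dict)

    @property
    def omnibus_p(self) -> float:
        return self.omnibus["anova_p" if "anova_p" in self.omnibus else "kruskal_p"]

    def pairwise_stars(self) -> dict[tuple[str, str], str]:
        return {pair: stars(p) for pair, p in self.pairwise.items()}

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "mode": self.mode,
            "groups": [
                {
                    "name": g,
                    "n": self.group_n[g],
                    "mean": self.group_mean[g],
                    "sem": self.group_sem[g],
                    "n_dropped": self.n_dropped.get(g, 0),
                }
                for g in self.group_names
            ],
            "omnibus": self.omnibus,
            "pairwise": [
                {"a": a, "b": b, "p_adj": p, "stars": stars(p)}
                for (a, b), p in self.pairwise.items()
            ],
        }

    def format_table(self) -> str:
        lines = [f"metric: {self.metric}   mode: {self.mode}"]
        for g in self.group_names:
            sem = self.group_sem[g]
            sem_s = f"{sem:.4g}" if sem is not None else "na"
            lines.append(
                f"  {g}: n={self.group_n[g]} mean={self.group_mean[g]:.4g} sem={sem_s}"
            )
        name, p = ("ANOVA F", self.omnibus.get("anova_F"))
        if "kruskal_H" in self.omnibus:
            name, p = ("Kruskal-Wallis H", self.omnibus["kruskal_H"])
        lines.append(f"  omnibus: {name}={p:.4g} p={self.omnibus_p:.4g} "
                     f"[{stars(self.omnibus_p)}]")
        for (a, b), padj in self.pairwise.items():
            lines.append(f"  {a} vs {b}: p_adj={padj:.4g} [{stars(padj)}]")
        return "\n".join(lines)


def _holm(pvals: list[float]) -> list[float]:
    """Holm step-down adjustment, monotone, clipped to 1."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def dunn_pairwise(
    groups: dict[str, np.ndarray], adjust: str = "holm"
) -> dict[tuple[str, str], float]:
    """Dunn's post-hoc test on pooled ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided normal p,
    then Holm (default) or Bonferroni adjustment.
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    rank_means, sizes = {}, {}
    offset = 0
    for g in names:
        n = groups[g].size
        rank_means[g] = ranks[offset: offset + n].mean()
        sizes[g] = n
        offset += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (rank_means[a] - rank_means[b]) / se if se > 0 else 0.0
        raw.append(2.0 * sps.norm.sf(abs(z)))
    if adjust == "holm":
        adj = _holm(raw)
    elif adjust == "bonferroni":
        adj = [min(p * len(raw), 1.0) for p in raw]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}; use 'holm' or 'bonferroni'")
    return dict(zip(pairs, adj))


def group_compare(
    groups: dict[str, list],
    metric: str = "",
    mode: str = "auto",
    dunn_adjust: str = "holm",
) -> GroupComparison:
    """Compare >= 2 named groups of values.

    mode: "parametric" (ANOVA + Tukey HSD), "nonparametric"
    (Kruskal-Wallis + Dunn), or "auto" (parametric unless any group
    fails Shapiro-Wilk at alpha = 0.05).  Missing values are dropped per
    group with the drop count recorded.
    """
    if mode not in ("parametric", "nonparametric", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups, got {len(groups)}")

    clean: dict[str, np.ndarray] = {}
    n_dropped: dict[str, int] = {}
    for name, values in groups.items():
        x = np.asarray(list(values), dtype=np.float64)
        finite = x[np.isfinite(x)]
        n_dropped[name] = int(x.size - finite.size)
        clean[name] = finite
    names = list(clean)

    if mode == "auto":
        mode = "parametric"
        for name, x in clean.items():
            # Shapiro needs >= 3 values and some spread
            if x.size >= 3 and np.ptp(x) > 0 and sps.shapiro(x).pvalue < 0.05:
                mode = "nonparametric"
                break

    for name, x in clean.items():
        minimum = 2 if mode == "parametric" else 1
        if x.size < minimum:
            raise ValueError(
                f"group {name!r} has {x.size} values; {mode} mode needs >= {minimum}"
            )

    samples = [clean[g] for g in names]
    if mode == "parametric":
        f_res = sps.f_oneway(*samples)
        omnibus = {"anova_F": float(f_res.statistic), "anova_p": float(f_res.pvalue)}
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            # identical constant groups: define the null identity F=0, p=1
            omnibus = {"anova_F": 0.0, "anova_p": 1.0}
        with np.errstate(invalid="ignore"):
            tukey = sps.tukey_hsd(*samples)
        pairwise = {}
        for i, j in itertools.combinations(range(len(names)), 2):
            p = float(tukey.pvalue[i, j])
            if math.isnan(p):
                # zero pooled variance with equal means: no evidence of difference
                p = 1.0
            pairwise[(names[i], names[j])] = p
    else:
        h_res = sps.kruskal(*samples)
        omnibus = {"kruskal_H": float(h_res.statistic), "kruskal_p": float(h_res.pvalue)}
        pairwise = dunn_pairwise(clean, adjust=dunn_adjust)

    means, sems = {}, {}
    for g in names:
        means[g], sems[g] = mean_sem(clean[g])
    return GroupComparison(
        metric=metric,
        mode=mode,
        group_names=names,
        group_n={g: int(clean[g].size) for g in names},
        group_mean=means,
        group_sem=sems,
        omnibus=omnibus,
        pairwise=pairwise,
        n_dropped=n_dropped,
    )
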