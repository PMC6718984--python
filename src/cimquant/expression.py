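"""Relative expression quantification: ddCt qPCR, blot densitometry, and
group comparison of expression levels.

The qPCR stage is the standard 2^-ddCt method: target Ct is normalised to a
housekeeping gene (Rpl41 in the assays this mirrors) within each sample, then
referenced to a calibrator sample so the calibrator's relative expression is
exactly 1.  Densitometry is normalised analogously to a loading control
(alpha-tubulin).  The group test compares log relative expression between
two groups of cultures (e.g. 3D-foci-forming vs contact-inhibited).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ddct", "blot_normalize", "group_expression_test"]


def ddct(ct_table: pd.DataFrame, reference_sample: str,
         gene_of_interest: str = "gene_of_interest",
         housekeeping: str = "housekeeping",
         efficiency: float = 2.0) -> pd.DataFrame:
    """Relative expression by the ddCt method.

    ``ct_table`` columns: sample_id, target, ct, replicate.  Replicate Ct
    values are averaged per sample x target before dCt = Ct_goi - Ct_hk;
    relative expression is ``efficiency ** -(dCt_sample - dCt_reference)``
    (amplification efficiency fixed at 2 by default, i.e. perfect doubling
    per cycle).  SEM is propagated from the replicate Ct variance of the
    sample's own two targets by the delta method, treating the reference
    dCt as the fixed calibrator baseline (so the reference maps to exactly
    1).  Returns a DataFrame with sample_id, rel_expr, sem.
    """
    df = ct_table.copy()
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    stats_tbl = df.groupby(["sample_id", "target"])["ct"].agg(["mean", "var", "count"])
    samples = df["sample_id"].unique()
    for s in samples:
        for t in (gene_of_interest, housekeeping):
            if (s, t) not in stats_tbl.index:
                raise ValueError(f"sample {s!r} is missing target {t!r}")
    if reference_sample not in samples:
        raise ValueError(f"reference sample {reference_sample!r} not in table")

    def dct(s):
        return (stats_tbl.loc[(s, gene_of_interest), "mean"]
                - stats_tbl.loc[(s, housekeeping), "mean"])

    ref_dct = dct(reference_sample)
    log_eff = np.log(efficiency)
    rows = []
    for s in samples:
        rel = efficiency ** -(dct(s) - ref_dct)
        var = 0.0
        for t in (gene_of_interest, housekeeping):
            v = stats_tbl.loc[(s, t), "var"]
            n = stats_tbl.loc[(s, t), "count"]
            if n > 1 and np.isfinite(v):
                var += v / n  # variance of the replicate-mean Ct
        sem = rel * log_eff * np.sqrt(var)  # delta method on 2^-x
        rows.append({"sample_id": s, "rel_expr": float(rel), "sem": float(sem)})
    return pd.DataFrame(rows)


def blot_normalize(densities: pd.DataFrame, reference_sample: str) -> pd.DataFrame:
    """Densitometry normalisation to a loading control and reference lane.

    ``densities`` columns: sample, target, loading_control (band
    intensities).  Level = (target/loading)_sample / (target/loading)_ref.
    """
    df = densities.copy()
    if (df["loading_control"] <= 0).any():
        raise ValueError("zero or negative loading-control intensity")
    if (df["target"] <= 0).any():
        raise ValueError("zero or negative target intensity")
    df = df.set_index("sample")
    if reference_sample not in df.index:
        raise ValueError(f"reference sample {reference_sample!r} not present")
    norm = df["target"] / df["loading_control"]
    ref = norm.loc[reference_sample]
    return pd.DataFrame({"sample": norm.index, "level": (norm / ref).to_numpy()})


def group_expression_test(rel_expr, groups, log_transform: bool = True,
                          method: str = "welch", n_permutations: int = 10_000,
                          seed: int | None = None) -> dict:
    """Two-sample comparison of relative expression between two groups.

    Values are log-transformed by default (expression fold changes are
    multiplicative).  ``method``: 'welch' (default), 'ranksum'
    (Mann-Whitney U) or 'permutation' (difference of means, label
    permutation null).  Effect is mean difference (second sorted group minus
    first) on the analysis scale.  Returns a dict with effect, statistic,
    p_value, method, groups.
    """
    x = np.asarray(rel_expr, dtype=float)
    g = np.asarray(groups, dtype=object)
    levels = sorted(set(g))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    if log_transform:
        if (x <= 0).any():
            raise ValueError("log transform requires positive values")
        x = np.log(x)
    a, b = x[g == levels[0]], x[g == levels[1]]
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 samples per group")
    effect = float(b.mean() - a.mean())
    if method == "welch":
        t, p = stats.ttest_ind(b, a, equal_var=False)
    elif method == "ranksum":
        t, p = stats.mannwhitneyu(b, a, alternative="two-sided")
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        obs = abs(effect)
        pooled = np.concatenate([a, b])
        hits = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            hits += abs(pooled[a.size:].mean() - pooled[:a.size].mean()) >= obs - 1e-12
        t, p = obs, (hits + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"effect": effect, "statistic": float(t), "p_value": float(p),
            "method": method, "groups": levels,
            "log_transform": log_transform}
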