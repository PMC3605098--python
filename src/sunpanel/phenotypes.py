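"""Per-location trait summaries, heritability, and trait correlations.

Phenotypes live in a long-format table with columns
(accession_id, location, rep, block, plant, trait, value).  Because
genotype-by-environment interaction is expected for field traits, entry
means and association inputs are produced separately per location.

LS-means come from an additive fixed-effects least-squares model
``value ~ entry + rep + block-within-rep`` (a deterministic surrogate for
a random-effects fit of the design terms; the two coincide for balanced
data).  Broad-sense heritability is total genotypic variance over total
phenotypic variance, estimated from the expected mean squares of a
one-way random-effects decomposition — by default on entry-by-location
means, so the residual absorbs GxE plus averaged plant noise.  Pearson
trait correlations are corrected with the Holm step-down (sequential
Bonferroni) procedure.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ["accession_id", "location", "rep", "block", "plant",
                     "trait", "value"]


def _check_table(p: pd.DataFrame) -> None:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in p.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")


def entry_means_and_lsmeans(
    p: pd.DataFrame, trait: str, location: str
) -> pd.DataFrame:
    """Per-accession raw means and LS-means for one trait at one location.

    The LS-mean is the model prediction for each entry averaged over every
    (rep, block) combination observed at the location, from an ordinary
    least-squares fit of ``value ~ entry + rep + block-within-rep``
    (solved with a pseudoinverse, so rank-deficient designs are handled).
    For balanced data LS-means equal raw means.
    """
    _check_table(p)
    sub = p[(p["trait"] == trait) & (p["location"] == location)].dropna(
        subset=["value"]
    )
    if sub.empty:
        raise ValueError(f"no data for trait {trait!r} at {location!r}")
    sub = sub.copy()
    sub["_rb"] = sub["rep"].astype(str) + ":" + sub["block"].astype(str)

    entries = sorted(sub["accession_id"].unique())
    rbs = sorted(sub["_rb"].unique())
    e_idx = sub["accession_id"].map({e: i for i, e in enumerate(entries)})
    rb_idx = sub["_rb"].map({r: i for i, r in enumerate(rbs)})

    n = len(sub)
    x = np.zeros((n, 1 + len(entries) - 1 + max(len(rbs) - 1, 0)))
    x[:, 0] = 1.0
    for row, e in enumerate(e_idx.to_numpy()):
        if e > 0:
            x[row, e] = 1.0
    off = len(entries)
    for row, r in enumerate(rb_idx.to_numpy()):
        if r > 0:
            x[row, off + r - 1] = 1.0
    y = sub["value"].to_numpy(dtype=float)
    beta = np.linalg.pinv(x) @ y

    # prediction grid: each entry crossed with every observed rep:block
    n_rb = len(rbs)
    rb_effects = np.concatenate([[0.0], beta[off:off + n_rb - 1]]) \
        if n_rb > 1 else np.zeros(1)
    mean_rb = rb_effects.mean()
    ls = np.empty(len(entries))
    for i in range(len(entries)):
        ent_eff = beta[i] if i > 0 else 0.0
        ls[i] = beta[0] + ent_eff + mean_rb

    raw = sub.groupby("accession_id")["value"].agg(["mean", "size"])
    out = pd.DataFrame(
        {
            "raw_mean": raw["mean"].reindex(entries).to_numpy(),
            "ls_mean": ls,
            "n_plants": raw["size"].reindex(entries).to_numpy(dtype=int),
        },
        index=pd.Index(entries, name="accession_id"),
    )
    return out


def entry_location_means(
    p: pd.DataFrame, trait: str, use_lsmeans: bool = False
) -> pd.DataFrame:
    """Accession x location table of entry means for one trait."""
    _check_table(p)
    sub = p[p["trait"] == trait]
    cols = {}
    for loc in sorted(sub["location"].unique()):
        em = entry_means_and_lsmeans(p, trait, loc)
        cols[loc] = em["ls_mean" if use_lsmeans else "raw_mean"]
    return pd.DataFrame(cols)


def broad_sense_heritability(
    p: pd.DataFrame, trait: str, scope: str = "across",
) -> tuple[float, dict]:
    """Broad-sense heritability H^2 = sigma2_G / (sigma2_G + sigma2_res).

    ``scope="across"`` decomposes entry-by-location means, with location
    main effects removed first (each location's column is centered) so the
    residual is GxE plus averaged within-plot noise, not the environmental
    mean differences; ``scope="within:<location>"`` decomposes plant-level
    values at one location.  Variance components come from expected mean
    squares of the one-way random-effects layout, with negative estimates
    truncated at 0.
    """
    _check_table(p)
    if scope == "across":
        means = entry_location_means(p, trait)
        means = means - means.mean(axis=0)
        long = means.stack().rename("value").reset_index()
        long.columns = ["accession_id", "location", "value"]
        groups = long.dropna(subset=["value"]).groupby("accession_id")["value"]
    elif scope.startswith("within:"):
        loc = scope.split(":", 1)[1]
        sub = p[(p["trait"] == trait) & (p["location"] == loc)]
        groups = sub.dropna(subset=["value"]).groupby("accession_id")["value"]
    else:
        raise ValueError(f"unknown scope {scope!r}")

    sizes = groups.size()
    sizes = sizes[sizes > 0]
    k = len(sizes)
    if k < 2:
        raise ValueError("need at least 2 entries for heritability")
    big_n = int(sizes.sum())
    values = groups.apply(list)
    all_vals = np.concatenate([np.asarray(v, dtype=float) for v in values])
    gmean = all_vals.mean()
    means_i = np.array([np.mean(v) for v in values])
    n_i = sizes.to_numpy(dtype=float)
    ss_between = float((n_i * (means_i - gmean) ** 2).sum())
    ss_within = float(sum(((np.asarray(v, dtype=float) - np.mean(v)) ** 2).sum()
                          for v in values))
    df_b, df_w = k - 1, big_n - k
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    n0 = (big_n - (n_i ** 2).sum() / big_n) / (k - 1)
    sigma_g = max(0.0, (ms_b - ms_w) / n0)
    sigma_res = ms_w
    h2 = sigma_g / (sigma_g + sigma_res) if sigma_g + sigma_res > 0 else 0.0
    return h2, {"sigma2_G": sigma_g, "sigma2_res": sigma_res,
                "MS_entry": ms_b, "MS_res": ms_w, "n0": n0,
                "n_entries": k, "n_obs": big_n}


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    _, adj, _, _ = multipletests(p, method="holm")
    return adj


def trait_correlations_holm(
    p: pd.DataFrame,
    cells: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pearson correlations between trait x location entry-mean vectors,
    with Holm-adjusted p-values over all tested pairs.

    ``cells`` lists the (trait, location) vectors to correlate; by default
    every trait x location combination present.  Vectors are accession
    means; pairs with fewer than 3 shared accessions or zero variance get
    NaN and are excluded from the Holm family.
    """
    _check_table(p)
    if cells is None:
        cells = sorted(
            {(t, l) for t, l in zip(p["trait"], p["location"])}
        )
    vectors = {}
    for trait, loc in cells:
        em = entry_means_and_lsmeans(p, trait, loc)
        vectors[(trait, loc)] = em["raw_mean"]

    rows = []
    keys = list(vectors)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = vectors[keys[i]], vectors[keys[j]]
            both = pd.concat([a, b], axis=1, join="inner").dropna()
            if len(both) < 3 or both.iloc[:, 0].std() == 0 \
                    or both.iloc[:, 1].std() == 0:
                r, pv = np.nan, np.nan
            else:
                r, pv = stats.pearsonr(both.iloc[:, 0], both.iloc[:, 1])
            rows.append({
                "trait_a": keys[i][0], "location_a": keys[i][1],
                "trait_b": keys[j][0], "location_b": keys[j][1],
                "n": len(both), "r": r, "p": pv,
            })
    out = pd.DataFrame(rows)
    out["p_holm"] = np.nan
    finite = out["p"].notna()
    if finite.sum():
        out.loc[finite, "p_holm"] = holm_adjust(out.loc[finite, "p"])
    return out
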