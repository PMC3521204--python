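"""Adenine-substitution statistics over detected DGR elements.

For each element the VR bases found at TR-adenine positions are counted
(unchanged A, or substitution to C, G, T).  Unchanged-A positions are reported
but are inherently uninterpretable: an A in the VR may come either from exact
base pairing or from random incorporation of an A.  Per-base frequencies are
averaged across elements with equal weight.

Two chi-square tests probe the substitution spectrum: a goodness-of-fit of
the pooled C/G/T substitution counts against equal expectation, and a
per-base test of whether each element's substitution count is proportional to
its TR adenine count (the no-selectivity expectation).  Raw p-values only; no
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

TARGETS = ("C", "G", "T")


@dataclass(frozen=True)
class SubstitutionProfile:
    n_elements: int
    per_element: pd.DataFrame   # n_A_tr, count_A..count_T, freq_A..freq_T, mutation_rate
    mean_freq: dict[str, float]
    sd_freq: dict[str, float]
    mean_mutation_rate: float


def profile(hits: Sequence) -> SubstitutionProfile:
    """Per-element base counts at TR-adenine positions, aggregated.

    All hits must carry wildcard base A (convert inverted hits with
    ``hit.on_element_strand()`` first).  Elements are weighted equally in the
    aggregate mean and standard deviation.
    """
    hits = list(hits)
    if not hits:
        raise InputError("no hits to profile")
    wildcards = {h.wildcard_base for h in hits}
    if wildcards != {"A"}:
        raise InputError(
            f"profile expects adenine-wildcard hits, got wildcards {sorted(wildcards)}"
        )
    rows = []
    for h in hits:
        n_a = h.n_wildcard_tr
        if n_a <= 0:
            raise InputError("hit with zero TR adenines cannot be profiled")
        counts = {b: 0 for b in "ACGT"}
        for _, _, v in h.substitutions:
            counts[v] += 1
        counts["A"] = n_a - len(h.substitutions)
        row = {"n_A_tr": n_a}
        row.update({f"count_{b}": counts[b] for b in "ACGT"})
        row.update({f"freq_{b}": counts[b] / n_a for b in "ACGT"})
        row["mutation_rate"] = len(h.substitutions) / n_a
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_freq = {b: float(df[f"freq_{b}"].mean()) for b in "ACGT"}
    sd_freq = {
        b: (float(df[f"freq_{b}"].std(ddof=1)) if len(df) > 1 else 0.0) for b in "ACGT"
    }
    return SubstitutionProfile(
        n_elements=len(df),
        per_element=df,
        mean_freq=mean_freq,
        sd_freq=sd_freq,
        mean_mutation_rate=float(df["mutation_rate"].mean()),
    )


def diversity(n_adenines: int) -> int:
    """Theoretical VR repertoire size for a TR with ``n_adenines`` mutable
    positions: each admits 4 outcomes, so 4**n, exactly."""
    if n_adenines < 0:
        raise InputError("adenine count must be >= 0")
    return 4 ** n_adenines


def chisq_uniform(counts: Mapping[str, int]) -> tuple[float, int, float]:
    """Goodness-of-fit of the three substitution-target counts to uniformity.

    Returns (statistic, df=2, p).
    """
    vals = [int(counts[b]) for b in sorted(counts)]
    if len(vals) != 3:
        raise InputError("expected counts for exactly three target bases")
    if sum(vals) < 1:
        raise InputError("all-zero counts: chi-square undefined")
    stat, p = sps.chisquare(vals)
    return float(stat), 2, float(p)


def _pool_cells(obs: np.ndarray, exp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge cells with expected < 1 into their smallest-expected neighbour.

    Cells are sorted by expectation and pooled smallest-first until every
    remaining cell has expectation >= 1 (or only one cell remains).
    """
    order = np.argsort(exp, kind="stable")
    obs, exp = list(obs[order]), list(exp[order])
    while len(exp) > 1 and exp[0] < 1.0:
        obs[1] += obs[0]
        exp[1] += exp[0]
        obs, exp = obs[1:], exp[1:]
        # keep sorted after the merge
        order = np.argsort(exp, kind="stable")
        obs = [obs[i] for i in order]
        exp = [exp[i] for i in order]
    return np.asarray(obs, dtype=float), np.asarray(exp, dtype=float)


def chisq_proportional(
    elements: Sequence[tuple[int, Mapping[str, int]]]
) -> dict[str, tuple[float, int, float]]:
    """Test, per target base, proportionality of counts to TR adenine content.

    ``elements`` is a sequence of (n_A_tr, counts-by-target).  Under no
    selectivity the expected count of base b in an element is the total count
    of b scaled by the element's share of adenines.  Cells with expectation
    below 1 are pooled.  Returns {base: (statistic, df, p)}.
    """
    if len(elements) < 2:
        raise InputError("need at least two elements")
    n_a = np.array([e[0] for e in elements], dtype=float)
    if (n_a <= 0).any():
        raise InputError("every element needs a positive TR adenine count")
    share = n_a / n_a.sum()
    out = {}
    for b in TARGETS:
        obs = np.array([float(e[1].get(b, 0)) for e in elements])
        total = obs.sum()
        if total <= 0:
            raise InputError(f"no {b} substitutions observed: test undefined")
        exp = total * share
        obs_p, exp_p = _pool_cells(obs, exp)
        if len(obs_p) < 2:
            raise InputError(f"degenerate single-cell table for base {b}")
        stat = float(((obs_p - exp_p) ** 2 / exp_p).sum())
        df = len(obs_p) - 1
        out[b] = (stat, df, float(sps.chi2.sf(stat, df)))
    return out


def profile_table(prof: SubstitutionProfile, path=None) -> pd.DataFrame:
    df = prof.per_element.copy()
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def stats_table(
    prof: SubstitutionProfile, path=None
) -> pd.DataFrame:
    """Aggregate frequencies plus both chi-square tests as one tidy table."""
    rows = [
        {
            "quantity": f"mean_freq_{b}",
            "value": prof.mean_freq[b],
            "sd": prof.sd_freq[b],
        }
        for b in "ACGT"
    ]
    pooled = {
        b: int(prof.per_element[f"count_{b}"].sum()) for b in TARGETS
    }
    if sum(pooled.values()) >= 1:
        stat, df_, p = chisq_uniform(pooled)
        rows.append({"quantity": "chisq_uniform_stat", "value": stat, "sd": ""})
        rows.append({"quantity": "chisq_uniform_df", "value": df_, "sd": ""})
        rows.append({"quantity": "chisq_uniform_p", "value": p, "sd": ""})
    if prof.n_elements >= 2:
        elements = [
            (int(r["n_A_tr"]), {b: int(r[f"count_{b}"]) for b in TARGETS})
            for _, r in prof.per_element.iterrows()
        ]
        try:
            per_base = chisq_proportional(elements)
        except InputError:
            per_base = {}
        for b, (stat, df_, p) in per_base.items():
            rows.append({"quantity": f"chisq_proportional_{b}_stat", "value": stat, "sd": ""})
            rows.append({"quantity": f"chisq_proportional_{b}_df", "value": df_, "sd": ""})
            rows.append({"quantity": f"chisq_proportional_{b}_p", "value": p, "sd": ""})
    df = pd.DataFrame(rows, columns=["quantity", "value", "sd"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
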