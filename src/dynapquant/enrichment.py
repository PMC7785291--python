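"""Spectral-count enrichment statistics for bait vs. GFP-control pulldowns.

Given PSM (peptide spectral match) counts from an affinity-purification
mass-spectrometry experiment and its matched GFP-only control, each protein
orthogroup *i* is scored with two statistics over the *n* groups observed in
the experiment:

* a pseudocounted log2 fold-change of compositional frequencies,

  ``FC_i = log2( ((E_i + 1) / sum_j (E_j + 1)) / ((C_i + 1) / sum_k (C_k + 1)) )``

  where ``E_i`` / ``C_i`` are the bait and control PSM counts of group *i*;

* a one-sided two-proportion Z statistic on the raw (un-pseudocounted)
  spectral-count frequencies ``f_i = PSM_i / sum_j PSM_j``,

  ``Z_i = (f_i,expt - f_i,ctrl) / sqrt( f_comb (1 - f_comb) / T_expt
                                      + f_comb (1 - f_comb) / T_ctrl )``

  with ``f_comb`` the pooled frequency and ``T`` the per-side totals.

Upper-tail normal p-values and Benjamini–Hochberg FDRs are attached, and a
group is called significant when its Z reaches the one-sided 95% critical
value (1.645 by default).  The two statistics deliberately differ in their
pseudocount treatment: the fold-change needs the +1 to stay finite for
groups absent on one side, while the Z test uses the observed proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import PairingSpec, apply_ortho_map, validate_psm_table

__all__ = [
    "Z_THRESHOLD_95",
    "CountPair",
    "collapse_to_groups",
    "combine_runs",
    "fold_change",
    "z_score",
    "p_value",
    "bh_adjust",
    "score_experiment",
    "log2_fc_from_counts",
    "z_from_counts",
]

#: one-sided standard-normal 95% critical value used as the default
#: significance gate (Phi^-1(0.95) = 1.6449 to 4 decimals)
Z_THRESHOLD_95 = 1.645


@dataclass
class CountPair:
    """Per-group summed bait vs. control PSM counts for one comparison.

    The universe is the union of groups with at least one PSM on either
    side; ``universe_size_n`` is its size, the *n* of the statistics.
    """

    group_ids: list[str]
    psm_expt: np.ndarray
    psm_ctrl: np.ndarray
    total_expt: int
    total_ctrl: int
    universe_size_n: int

    @classmethod
    def from_counts(cls, group_ids, psm_expt, psm_ctrl) -> "CountPair":
        e = np.asarray(psm_expt, dtype=np.int64)
        c = np.asarray(psm_ctrl, dtype=np.int64)
        if e.shape != c.shape or e.ndim != 1 or len(group_ids) != e.size:
            raise ValueError("group_ids, psm_expt and psm_ctrl must have equal length")
        if (e < 0).any() or (c < 0).any():
            raise ValueError("PSM counts must be non-negative")
        if ((e + c) < 1).any():
            raise ValueError("every group in the universe needs >=1 PSM overall")
        return cls(
            group_ids=list(group_ids),
            psm_expt=e,
            psm_ctrl=c,
            total_expt=int(e.sum()),
            total_ctrl=int(c.sum()),
            universe_size_n=int(e.size),
        )


def collapse_to_groups(table: pd.DataFrame, ortho_map: dict[str, str]) -> pd.DataFrame:
    """Collapse a PSM table to orthology groups.

    PSMs are summed within (run_id, group_id); runs are never merged here.
    Proteins missing from the map become singleton groups named after the
    protein (with a warning).
    """
    df = validate_psm_table(table)
    df["protein_id"] = apply_ortho_map(df["protein_id"], ortho_map)
    out = (
        df.groupby(["run_id", "bait_label", "protein_id"], sort=True, as_index=False)[
            "psm_count"
        ]
        .sum()
        .sort_values(["run_id", "protein_id"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def combine_runs(
    table: pd.DataFrame, spec: PairingSpec, bait_label: str
) -> CountPair:
    """Pool replicate runs into one bait-vs-control count pair.

    PSMs are summed across the bait runs and across the control runs of the
    pairing; the universe is the union of groups seen on either side, with
    zeros filled in for groups absent on one side.
    """
    pairing = spec.for_bait(bait_label)
    runs_present = set(table["run_id"])
    for rid in (*pairing.bait_run_ids, *pairing.control_run_ids):
        if rid not in runs_present:
            raise KeyError(f"run id {rid!r} not present in the PSM table")

    def side(run_ids) -> pd.Series:
        sub = table[table["run_id"].isin(run_ids)]
        return sub.groupby("protein_id")["psm_count"].sum()

    expt = side(pairing.bait_run_ids)
    ctrl = side(pairing.control_run_ids)
    universe = sorted(set(expt.index) | set(ctrl.index))
    e = expt.reindex(universe, fill_value=0).to_numpy(dtype=np.int64)
    c = ctrl.reindex(universe, fill_value=0).to_numpy(dtype=np.int64)
    keep = (e + c) >= 1  # groups listed with 0 PSMs on both sides drop out
    return CountPair.from_counts(
        [g for g, k in zip(universe, keep) if k], e[keep], c[keep]
    )


def log2_fc_from_counts(expt, ctrl, axis: int = -1) -> np.ndarray:
    """Pseudocounted log2 fold-change of compositional frequencies.

    Accepts stacked count arrays with groups along ``axis``, enabling batch
    scoring of many universes at once.
    """
    e = np.asarray(expt, dtype=np.float64) + 1.0
    c = np.asarray(ctrl, dtype=np.float64) + 1.0
    fe = e / e.sum(axis=axis, keepdims=True)
    fc = c / c.sum(axis=axis, keepdims=True)
    return np.log2(fe / fc)


def z_from_counts(expt, ctrl, axis: int = -1) -> np.ndarray:
    """One-sided two-proportion Z on raw spectral-count frequencies.

    Z is defined as 0 wherever the pooled frequency is 0 or 1 (degenerate
    variance).  Requires a positive total on each side along ``axis``.
    """
    e = np.asarray(expt, dtype=np.float64)
    c = np.asarray(ctrl, dtype=np.float64)
    te = e.sum(axis=axis, keepdims=True)
    tc = c.sum(axis=axis, keepdims=True)
    if (te < 1).any() or (tc < 1).any():
        raise ValueError("both bait and control totals must be >= 1")
    fe = e / te
    fc = c / tc
    fcomb = (e + c) / (te + tc)
    var = fcomb * (1.0 - fcomb) * (1.0 / te + 1.0 / tc)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (fe - fc) / np.sqrt(var)
    return np.where(var > 0.0, z, 0.0)


def fold_change(cp: CountPair) -> np.ndarray:
    """Per-group log2 fold-change (bits); finite by construction."""
    return log2_fc_from_counts(cp.psm_expt, cp.psm_ctrl)


def z_score(cp: CountPair) -> np.ndarray:
    """Per-group Z statistic (0 where the pooled frequency is degenerate)."""
    return z_from_counts(cp.psm_expt, cp.psm_ctrl)


def p_value(z) -> np.ndarray | float:
    """Upper-tail standard-normal p-value, ``p = 1 - Phi(z)``."""
    z = np.asarray(z, dtype=np.float64)
    if not np.isfinite(z).all():
        raise ValueError("z must be finite")
    p = stats.norm.sf(z)
    return float(p) if p.ndim == 0 else p


def bh_adjust(p, axis: int = -1) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR q-values).

    Standard step-up: sort ascending, take ``min(1, p_(j) * m / j)`` and
    enforce monotonicity from the largest rank down, then map back to the
    original order.  Accepts stacked p-value arrays with tests along
    ``axis`` for batch adjustment of many experiments at once.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.shape[axis]
    order = np.argsort(p, axis=axis, kind="stable")
    ranked = np.take_along_axis(p, order, axis=axis)
    shape = [1] * p.ndim
    shape[axis] = m
    scaled = ranked * (m / np.arange(1, m + 1, dtype=np.float64)).reshape(shape)
    q_sorted = np.flip(
        np.minimum.accumulate(np.flip(scaled, axis=axis), axis=axis), axis=axis
    )
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    np.put_along_axis(q, order, q_sorted, axis=axis)
    return q


def score_experiment(
    table: pd.DataFrame,
    ortho_map: dict[str, str],
    spec: PairingSpec,
    bait_label: str,
    bait_group_id: str,
    z_threshold: float = Z_THRESHOLD_95,
) -> pd.DataFrame:
    """Score one bait pulldown end to end.

    Collapses to orthogroups, pools replicate runs, computes fold-changes,
    Z statistics, p-values and BH FDRs, flags the bait row and significance
    (``z >= z_threshold``), and ranks rows by z descending (ties broken by
    log2_fc descending, then group id).

    Returns a DataFrame with columns group_id, psm_expt, psm_ctrl, f_expt,
    f_ctrl, f_comb, log2_fc, z, p, fdr, significant, is_bait.
    """
    collapsed = collapse_to_groups(table, ortho_map)
    cp = combine_runs(collapsed, spec, bait_label)
    e = cp.psm_expt.astype(np.float64)
    c = cp.psm_ctrl.astype(np.float64)
    f_expt = e / cp.total_expt
    f_ctrl = c / cp.total_ctrl
    f_comb = (e + c) / (cp.total_expt + cp.total_ctrl)
    z = z_score(cp)
    p = p_value(z)
    degenerate = (f_comb <= 0.0) | (f_comb >= 1.0)
    p = np.where(degenerate, 1.0, p)  # statistic undefined: conservative
    res = pd.DataFrame(
        {
            "group_id": cp.group_ids,
            "psm_expt": cp.psm_expt,
            "psm_ctrl": cp.psm_ctrl,
            "f_expt": f_expt,
            "f_ctrl": f_ctrl,
            "f_comb": f_comb,
            "log2_fc": fold_change(cp),
            "z": z,
            "p": p,
            "fdr": bh_adjust(p),
            "significant": z >= z_threshold,
            "is_bait": [g == bait_group_id for g in cp.group_ids],
        }
    )
    res = res.sort_values(
        ["z", "log2_fc", "group_id"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    return res
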