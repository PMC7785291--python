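"""Readers and writers for the tabular artifacts of the pipeline.

All tables are UTF-8, tab-separated, with a single header line.  Real-valued
columns are serialized with 6 significant digits so that a write/read round
trip reproduces them to better than 1e-6 relative error.

The three input artifacts are:

* a PSM table — long-form peptide-spectral-match counts per
  (run, bait label, protein), as exported from an upstream search engine;
* an orthogroup map — a two-column ``protein_id -> group_id`` table used to
  collapse homeologs and closely related entries before statistics;
* a pairing table — which runs are bait pulldowns and which are the matched
  GFP-only controls for each bait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PSM_COLUMNS",
    "RESULT_COLUMNS",
    "TableFormatError",
    "TableValueError",
    "DuplicateRowError",
    "OrthoMapConflictError",
    "Pairing",
    "PairingSpec",
    "read_psm_table",
    "write_psm_table",
    "validate_psm_table",
    "read_ortho_map",
    "write_ortho_map",
    "read_pairing",
    "write_pairing",
    "write_results",
    "read_results",
]

PSM_COLUMNS = ["run_id", "bait_label", "protein_id", "psm_count"]

RESULT_COLUMNS = [
    "group_id", "psm_expt", "psm_ctrl", "f_expt", "f_ctrl", "f_comb",
    "log2_fc", "z", "p", "fdr", "significant", "is_bait",
]

#: 6 significant digits for all serialized reals
_FLOAT_FMT = "%.6g"


class TableFormatError(ValueError):
    """A required column is missing or the file layout is wrong."""


class TableValueError(ValueError):
    """A cell holds an out-of-contract value (cites the offending line)."""


class DuplicateRowError(ValueError):
    """The same (run_id, protein_id) appears more than once."""


class OrthoMapConflictError(ValueError):
    """A protein is mapped to two different orthology groups."""


@dataclass(frozen=True)
class Pairing:
    """Bait/control run assignment for one pulldown experiment."""

    bait_label: str
    bait_run_ids: tuple[str, ...]
    control_run_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.bait_run_ids or not self.control_run_ids:
            raise TableValueError(
                f"pairing for bait {self.bait_label!r}: bait and control "
                "run lists must both be non-empty"
            )
        if set(self.bait_run_ids) & set(self.control_run_ids):
            raise TableValueError(
                f"pairing for bait {self.bait_label!r}: bait and control "
                "runs must be disjoint"
            )


@dataclass
class PairingSpec:
    """All bait/control pairings of a study."""

    pairs: list[Pairing] = field(default_factory=list)

    def for_bait(self, bait_label: str) -> Pairing:
        for p in self.pairs:
            if p.bait_label == bait_label:
                return p
        raise KeyError(f"no pairing defined for bait label {bait_label!r}")


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")


def validate_psm_table(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Validate a PSM table held in a DataFrame and return it unchanged.

    Enforces the two table invariants: integer counts >= 0 and uniqueness of
    (run_id, protein_id).  Row numbers in error messages are 1-based data
    rows (the header is line 1, the first data row line 2).
    """
    _require_columns(df, PSM_COLUMNS, source)
    counts = df["psm_count"]
    numeric = pd.to_numeric(counts, errors="coerce")
    bad = numeric.isna() | (numeric < 0) | (numeric != numeric.round())
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise TableValueError(
            f"{source}, line {i + 2}: psm_count must be a non-negative "
            f"integer, got {counts.iloc[i]!r}"
        )
    dup = df.duplicated(subset=["run_id", "protein_id"], keep=False)
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise DuplicateRowError(
            f"{source}, line {i + 2}: duplicate (run_id, protein_id) pair "
            f"({df['run_id'].iloc[i]!r}, {df['protein_id'].iloc[i]!r})"
        )
    out = df.loc[:, PSM_COLUMNS].copy()
    out["psm_count"] = numeric.astype(np.int64)
    return out


def read_psm_table(path) -> pd.DataFrame:
    """Read a tab-separated PSM table with columns run_id, bait_label,
    protein_id, psm_count.  Row order is preserved."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, keep_default_na=False)
    df = df.rename(columns=lambda c: c.strip())
    _require_columns(df, PSM_COLUMNS, path)
    for col in ("run_id", "bait_label", "protein_id"):
        df[col] = df[col].astype(str)
    return validate_psm_table(df, source=str(path))


def write_psm_table(df: pd.DataFrame, path) -> None:
    """Write a validated PSM table as TSV."""
    validate_psm_table(df).to_csv(path, sep="\t", index=False)


def read_ortho_map(path) -> dict[str, str]:
    """Read a two-column (protein_id, group_id) TSV into a dict.

    Duplicate identical rows are tolerated; the same protein mapped to two
    different groups raises :class:`OrthoMapConflictError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["protein_id", "group_id"], path)
    mapping: dict[str, str] = {}
    for i, (prot, grp) in enumerate(zip(df["protein_id"], df["group_id"])):
        prev = mapping.get(prot)
        if prev is not None and prev != grp:
            raise OrthoMapConflictError(
                f"{path}, line {i + 2}: protein {prot!r} mapped to both "
                f"{prev!r} and {grp!r}"
            )
        mapping[prot] = grp
    return mapping


def write_ortho_map(mapping: dict[str, str], path) -> None:
    pd.DataFrame(
        {"protein_id": list(mapping), "group_id": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def read_pairing(path) -> PairingSpec:
    """Read a pairing table with columns bait_label, role, run_id.

    ``role`` is either ``bait`` or ``control``.  Run order within a role is
    preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["bait_label", "role", "run_id"], path)
    bad_role = ~df["role"].isin(["bait", "control"])
    if bad_role.any():
        i = int(np.flatnonzero(bad_role.to_numpy())[0])
        raise TableValueError(
            f"{path}, line {i + 2}: role must be 'bait' or 'control', "
            f"got {df['role'].iloc[i]!r}"
        )
    pairs = []
    for label, sub in df.groupby("bait_label", sort=False):
        pairs.append(
            Pairing(
                bait_label=str(label),
                bait_run_ids=tuple(sub.loc[sub["role"] == "bait", "run_id"]),
                control_run_ids=tuple(sub.loc[sub["role"] == "control", "run_id"]),
            )
        )
    return PairingSpec(pairs)


def write_pairing(spec: PairingSpec, path) -> None:
    rows = []
    for p in spec.pairs:
        rows += [(p.bait_label, "bait", r) for r in p.bait_run_ids]
        rows += [(p.bait_label, "control", r) for r in p.control_run_ids]
    pd.DataFrame(rows, columns=["bait_label", "role", "run_id"]).to_csv(
        path, sep="\t", index=False
    )


def apply_ortho_map(protein_ids: pd.Series, mapping: dict[str, str]) -> pd.Series:
    """Map protein ids to group ids; unmapped proteins become singleton
    groups (group_id = protein_id) with a warning."""
    mapped = protein_ids.map(mapping)
    unmapped = mapped.isna()
    if unmapped.any():
        warnings.warn(
            f"{int(unmapped.sum())} protein id(s) absent from the orthogroup "
            "map were kept as singleton groups",
            stacklevel=2,
        )
        mapped = mapped.where(~unmapped, protein_ids)
    return mapped.astype(str)


def write_results(results: pd.DataFrame, path, edges_path=None) -> None:
    """Write an enrichment results table and, optionally, a network edge list.

    The edge list holds one edge per significant non-bait group, weighted by
    its log2 fold-change — the numbers behind a bait–prey "spoke" diagram.
    """
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise TableFormatError(f"results table missing column(s) {missing}")
    if results[RESULT_COLUMNS].isna().any().any():
        raise TableValueError("results table has missing statistics")
    results[RESULT_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )
    if edges_path is not None:
        keep = results["significant"].astype(bool) & ~results["is_bait"].astype(bool)
        bait_rows = results.loc[results["is_bait"].astype(bool), "group_id"]
        bait = bait_rows.iloc[0] if len(bait_rows) else ""
        edges = pd.DataFrame(
            {
                "bait": bait,
                "prey": results.loc[keep, "group_id"],
                "weight": results.loc[keep, "log2_fc"],
            }
        )
        edges.to_csv(edges_path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"group_id": str})
    _require_columns(df, RESULT_COLUMNS, path)
    df["significant"] = df["significant"].astype(bool)
    df["is_bait"] = df["is_bait"].astype(bool)
    return df
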