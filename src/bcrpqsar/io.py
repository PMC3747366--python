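"""Compound tables and block-organized descriptor matrices.

The central containers are :class:`CompoundRecord` (one compound with a
binary substrate/nonsubstrate label) and :class:`DescriptorMatrix`
(compounds x named descriptors, with the descriptor names partitioned
into named blocks mirroring the families a descriptor program emits).
Both round-trip through plain CSV, with the block structure serialized
as a JSON sidecar, so synthetic and real inputs are interchangeable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBSTRATE = 1
NONSUBSTRATE = -1

_VALID_SETS = {"train", "test", "decoy", "unassigned"}


@dataclass
class CompoundRecord:
    """One compound: identifier, optional SMILES, class label, assignments.

    ``label`` is +1 for substrates and -1 for nonsubstrates.  Decoys are
    putative substrates, so they carry label +1 with
    ``provenance="putative"``.
    """

    id: str
    label: int
    smiles: str | None = None
    set: str = "unassigned"
    cluster: int | None = None
    provenance: str = "known"

    def __post_init__(self) -> None:
        if self.label not in (SUBSTRATE, NONSUBSTRATE):
            raise ValueError(f"label must be +1 or -1, got {self.label!r}")
        if self.set not in _VALID_SETS:
            raise ValueError(f"set must be one of {_VALID_SETS}, got {self.set!r}")


def read_compounds(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table CSV (columns: id, label; optional smiles, set).

    Labels may be ``1``/``-1`` or the string ``putative`` (a decoy,
    i.e. a putative substrate stored as label +1 with a provenance flag).

    Raises
    ------
    ValueError
        On duplicate ids (the offending id is named) or an unparsable
        label (the row number is named).
    """
    df = pd.read_csv(path, dtype={"id": str})
    if df.empty:
        warnings.warn(f"{path}: empty compound table", stacklevel=2)
        return []
    if "id" not in df.columns or "label" not in df.columns:
        raise ValueError(f"{path}: compound CSV requires 'id' and 'label' columns")
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate compound id {dup.iloc[0]!r}")
    records: list[CompoundRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        raw = str(row.label).strip()
        provenance = "known"
        if raw.lower() == "putative":
            label = SUBSTRATE
            provenance = "putative"
        else:
            try:
                label = int(float(raw))
            except ValueError:
                raise ValueError(f"row {row_no}: unparsable label {raw!r}") from None
            if label not in (SUBSTRATE, NONSUBSTRATE):
                raise ValueError(f"row {row_no}: label {label} not in {{+1, -1}}")
        smiles = getattr(row, "smiles", None)
        if smiles is not None and (pd.isna(smiles) or smiles == ""):
            smiles = None
        set_ = getattr(row, "set", "unassigned")
        if set_ is None or pd.isna(set_):
            set_ = "unassigned"
        records.append(
            CompoundRecord(
                id=str(row.id), label=label, smiles=smiles, set=str(set_), provenance=provenance
            )
        )
    return records


def write_compounds(records: Iterable[CompoundRecord], path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "smiles": r.smiles if r.smiles is not None else "",
            "label": "putative" if r.provenance == "putative" else r.label,
            "set": r.set,
            "cluster": r.cluster if r.cluster is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


class DescriptorMatrix:
    """Dense compounds x descriptors matrix with a block partition.

    Every descriptor name belongs to exactly one named block; the union
    of the blocks equals the descriptor names.  Values are 64-bit floats.
    """

    def __init__(self, values: pd.DataFrame, blocks: Mapping[str, Sequence[str]]):
        blocks = {k: list(v) for k, v in blocks.items()}
        names: list[str] = []
        for block_names in blocks.values():
            names.extend(block_names)
        if sorted(names) != sorted(values.columns):
            raise ValueError("blocks must partition the descriptor names exactly")
        if len(set(names)) != len(names):
            raise ValueError("a descriptor may belong to only one block")
        self.values = values.astype(np.float64)
        self.blocks = blocks

    # ------------------------------------------------------------------
    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def block_of(self, descriptor: str) -> str:
        for block, names in self.blocks.items():
            if descriptor in names:
                return block
        raise KeyError(descriptor)

    def subset_descriptors(self, names: Sequence[str]) -> "DescriptorMatrix":
        keep = set(names)
        blocks = {
            b: [n for n in ns if n in keep] for b, ns in self.blocks.items()
        }
        blocks = {b: ns for b, ns in blocks.items() if ns}
        return DescriptorMatrix(self.values[list(names)], blocks)

    def subset_compounds(self, ids: Sequence[str]) -> "DescriptorMatrix":
        return DescriptorMatrix(self.values.loc[list(ids)], self.blocks)

    # ------------------------------------------------------------------
    def to_csv(self, path: str | Path, manifest_path: str | Path | None = None) -> None:
        """Write the matrix as CSV plus a JSON block manifest sidecar."""
        path = Path(path)
        if manifest_path is None:
            manifest_path = path.with_suffix(".blocks.json")
        self.values.to_csv(path, index_label="id", float_format="%.12g")
        Path(manifest_path).write_text(json.dumps(self.blocks, indent=1))

    @classmethod
    def from_csv(
        cls, path: str | Path, manifest_path: str | Path | None = None
    ) -> "DescriptorMatrix":
        path = Path(path)
        if manifest_path is None:
            manifest_path = path.with_suffix(".blocks.json")
        values = pd.read_csv(path, index_col="id")
        values.index = values.index.astype(str)
        values.index.name = None
        blocks = json.loads(Path(manifest_path).read_text())
        return cls(values, blocks)


@dataclass
class LowInformationFilter:
    """Rule removing constant / near-constant descriptors.

    A descriptor is dropped when its variance on the *training rows* is
    below ``variance_tol`` or its modal value covers more than
    ``modal_fraction`` of the training rows.  Filtering decisions never
    look at test-set rows.
    """

    variance_tol: float = 1e-8
    modal_fraction: float = 0.95

    def passes(self, column: np.ndarray) -> bool:
        col = np.asarray(column, dtype=np.float64)
        sd = col.std()
        scaled = col / sd if sd > 0 else col
        if np.var(scaled) < self.variance_tol:
            return False
        _, counts = np.unique(col, return_counts=True)
        return counts.max() / len(col) <= self.modal_fraction


def filter_low_information(
    matrix: DescriptorMatrix,
    training_ids: Sequence[str],
    rule: LowInformationFilter | None = None,
) -> DescriptorMatrix:
    """Drop low-information descriptors, judged on training rows only."""
    rule = rule or LowInformationFilter()
    missing = set(training_ids) - set(matrix.compound_ids)
    if missing:
        raise ValueError(f"training ids not in matrix: {sorted(missing)[:5]}")
    train = matrix.values.loc[list(training_ids)]
    keep = [name for name in matrix.descriptor_names if rule.passes(train[name].to_numpy())]
    if not keep:
        raise ValueError("no informative descriptors remain after filtering")
    dropped = matrix.shape[1] - len(keep)
    if dropped:
        logger.info("filter_low_information: removed %d descriptors", dropped)
    return matrix.subset_descriptors(keep)


def impute_nonfinite(matrix: DescriptorMatrix, training_ids: Sequence[str]) -> DescriptorMatrix:
    """Replace non-finite values with the training-set median per descriptor."""
    values = matrix.values.copy()
    arr = values.to_numpy()
    bad = ~np.isfinite(arr)
    if bad.any():
        train = values.loc[list(training_ids)].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(np.where(np.isfinite(train), train, np.nan), axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        arr[bad] = np.broadcast_to(med, arr.shape)[bad]
        logger.info("imputed %d non-finite descriptor values", int(bad.sum()))
        values.iloc[:, :] = arr
    return DescriptorMatrix(values, matrix.blocks)
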