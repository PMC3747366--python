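"""Open, block-organized 0D-2D molecular descriptors from SMILES.

Computes a conformation-independent descriptor set with RDKit and
organizes it into named blocks mirroring the families a commercial
descriptor program emits: constitutional counts,
topological indices, connectivity (chi) indices, 2D autocorrelations,
functional-group counts, Burden-matrix eigenvalue (BCUT) descriptors,
molecular properties, electrotopological-state descriptors and
kappa shape indices.  No 3D / conformation-dependent descriptor is
ever produced, so no conformer generation is needed before prediction.

The downstream pipeline is parameterized by the block manifest, never
by specific descriptor identities, so any other block-organized set
can be substituted through the CSV + manifest interface.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

from .io import CompoundRecord, DescriptorMatrix

logger = logging.getLogger(__name__)

_DESC_FUNCS = dict(Descriptors.descList)

_N_AUTOCORR2D = 192

# Named blocks of RDKit descriptor names.  Each descriptor appears in
# exactly one block; the 2D-autocorrelation block is handled separately
# because it comes from a vector-valued calculator.
BLOCK_DEFINITIONS: Mapping[str, Sequence[str]] = {
    "constitutional": [
        "MolWt", "ExactMolWt", "HeavyAtomCount", "NumHAcceptors", "NumHDonors",
        "NHOHCount", "NOCount", "NumHeteroatoms", "NumRotatableBonds",
        "RingCount", "NumAromaticRings", "NumAliphaticRings",
        "NumSaturatedRings", "FractionCSP3", "NumValenceElectrons",
    ],
    "topological": ["BalabanJ", "BertzCT", "AvgIpc", "HallKierAlpha"],
    "connectivity": [
        "Chi0", "Chi1", "Chi0n", "Chi1n", "Chi2n", "Chi3n", "Chi4n",
        "Chi0v", "Chi1v", "Chi2v", "Chi3v", "Chi4v",
    ],
    "functional_groups": sorted(n for n in _DESC_FUNCS if n.startswith("fr_")),
    "burden_eigenvalues": [
        "BCUT2D_MWHI", "BCUT2D_MWLOW", "BCUT2D_CHGHI", "BCUT2D_CHGLO",
        "BCUT2D_LOGPHI", "BCUT2D_LOGPLOW", "BCUT2D_MRHI", "BCUT2D_MRLOW",
    ],
    "molecular_properties": [
        "MolLogP", "MolMR", "TPSA", "LabuteASA",
        "MaxPartialCharge", "MinPartialCharge",
        "MaxAbsPartialCharge", "MinAbsPartialCharge",
    ],
    "estate": sorted(
        ["MaxEStateIndex", "MinEStateIndex", "MaxAbsEStateIndex", "MinAbsEStateIndex"]
        + [f"EState_VSA{i}" for i in range(1, 12)]
        + [f"VSA_EState{i}" for i in range(1, 11)]
    ),
    "kappa_shape": ["Kappa1", "Kappa2", "Kappa3"],
}


def default_block_names() -> list[str]:
    return list(BLOCK_DEFINITIONS) + ["autocorrelation_2d"]


def compute_descriptor_blocks(
    records: Iterable[CompoundRecord],
    blocks: Sequence[str] | None = None,
    impute: bool = True,
) -> DescriptorMatrix:
    """Compute the selected descriptor blocks for compounds with SMILES.

    Parameters
    ----------
    records
        Compounds; every record must carry a parsable SMILES.
    blocks
        Block names to compute (default: all).
    impute
        Replace non-finite descriptor values by the column median over
        the computed compounds (logged).  LDA requires dense matrices.

    Raises
    ------
    ValueError
        If any SMILES fails to parse; all offending ids are listed.
    """
    records = list(records)
    block_sel = list(blocks) if blocks is not None else default_block_names()
    unknown = set(block_sel) - set(default_block_names())
    if unknown:
        raise ValueError(f"unknown descriptor blocks: {sorted(unknown)}")

    mols, bad = [], []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles) if rec.smiles else None
        if mol is None:
            bad.append(rec.id)
        mols.append(mol)
    if bad:
        raise ValueError(f"invalid SMILES for compounds: {bad}")

    scalar_names = [
        name for b in block_sel if b != "autocorrelation_2d" for name in BLOCK_DEFINITIONS[b]
    ]
    rows = []
    for mol in mols:
        row = []
        for name in scalar_names:
            try:
                row.append(float(_DESC_FUNCS[name](mol)))
            except Exception:  # a descriptor failing on an odd molecule
                row.append(np.nan)
        if "autocorrelation_2d" in block_sel:
            try:
                row.extend(rdMolDescriptors.CalcAUTOCORR2D(mol))
            except Exception:
                row.extend([np.nan] * _N_AUTOCORR2D)
        rows.append(row)

    columns = list(scalar_names)
    if "autocorrelation_2d" in block_sel:
        columns += [f"AUTOCORR2D_{i}" for i in range(1, _N_AUTOCORR2D + 1)]
    values = pd.DataFrame(rows, index=[r.id for r in records], columns=columns, dtype=np.float64)

    if impute:
        arr = values.to_numpy()
        nonfinite = ~np.isfinite(arr)
        if nonfinite.any():
            col_med = np.nanmedian(np.where(np.isfinite(arr), arr, np.nan), axis=0)
            col_med = np.where(np.isfinite(col_med), col_med, 0.0)
            arr[nonfinite] = np.broadcast_to(col_med, arr.shape)[nonfinite]
            values.iloc[:, :] = arr
            logger.info("imputed %d non-finite descriptor values", int(nonfinite.sum()))

    manifest = {
        b: (
            [f"AUTOCORR2D_{i}" for i in range(1, _N_AUTOCORR2D + 1)]
            if b == "autocorrelation_2d"
            else list(BLOCK_DEFINITIONS[b])
        )
        for b in block_sel
    }
    return DescriptorMatrix(values, manifest)


# The nine structure-representation properties used for the k-means
# refinement of the rational dataset split: molecular weight, log P,
# polar surface area, H-bond acceptor and donor counts, an atomic
# composition information index (stand-in: BertzCT), sum of atomic
# van-der-Waals volumes (stand-in: LabuteASA), sum of atomic Sanderson
# electronegativities (stand-in: total valence-electron count) and a
# 2D shape index (stand-in: Kappa2).
PARTITION_PROPERTY_DESCRIPTORS: tuple[str, ...] = (
    "MolWt", "MolLogP", "TPSA", "NumHAcceptors", "NumHDonors",
    "BertzCT", "LabuteASA", "NumValenceElectrons", "Kappa2",
)
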