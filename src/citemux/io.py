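"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices use the 10x-style triplet layout: one Matrix-Market file
(features x droplets) plus ``barcodes.tsv`` and ``features.tsv``, where the
features file carries a third column naming the modality of each feature
(``Gene Expression``, ``Antibody Capture`` or ``Hashtag``). Tabular outputs
are plain TSV.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)

GENE_EXPRESSION = "Gene Expression"
ANTIBODY_CAPTURE = "Antibody Capture"
HASHTAG = "Hashtag"
_MODALITIES = (GENE_EXPRESSION, ANTIBODY_CAPTURE, HASHTAG)


@dataclass
class MultiModalCounts:
    """Aligned RNA / surface-protein (ADT) / hashtag (HTO) count matrices.

    All three matrices are features x droplets, share the identical barcode
    ordering, and hold nonnegative integer counts (CSR sparse).
    """

    barcodes: pd.Index
    rna: sp.csr_matrix
    adt: sp.csr_matrix
    hto: sp.csr_matrix
    gene_names: pd.Index
    adt_names: pd.Index
    hto_names: pd.Index

    def __post_init__(self) -> None:
        self.barcodes = pd.Index(self.barcodes, name="barcode")
        self.gene_names = pd.Index(self.gene_names)
        self.adt_names = pd.Index(self.adt_names)
        self.hto_names = pd.Index(self.hto_names)
        n = len(self.barcodes)
        for attr, names in (("rna", self.gene_names), ("adt", self.adt_names),
                            ("hto", self.hto_names)):
            m = sp.csr_matrix(getattr(self, attr))
            if m.shape != (len(names), n):
                raise ValueError(
                    f"{attr} matrix shape {m.shape} does not match "
                    f"{len(names)} features x {n} barcodes")
            if m.nnz and m.data.min() < 0:
                raise ValueError(f"{attr} matrix contains negative counts")
            if not np.allclose(m.data, np.round(m.data)):
                raise ValueError(f"{attr} matrix contains non-integer counts")
            setattr(self, attr, m)

    @property
    def n_droplets(self) -> int:
        return len(self.barcodes)

    def subset(self, barcodes: pd.Index) -> "MultiModalCounts":
        """Return a copy restricted to ``barcodes`` (in the given order)."""
        idx = self.barcodes.get_indexer(pd.Index(barcodes))
        if (idx < 0).any():
            missing = list(pd.Index(barcodes)[idx < 0][:5])
            raise KeyError(f"unknown barcodes: {missing}")
        return MultiModalCounts(
            barcodes=self.barcodes[idx],
            rna=self.rna[:, idx], adt=self.adt[:, idx], hto=self.hto[:, idx],
            gene_names=self.gene_names, adt_names=self.adt_names,
            hto_names=self.hto_names)


def write_multimodal(counts: MultiModalCounts, out_dir: str | Path) -> None:
    """Write matrix.mtx + barcodes.tsv + features.tsv (10x-style triplet)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stacked = sp.vstack([counts.rna, counts.adt, counts.hto]).tocoo()
    scipy.io.mmwrite(str(out / "matrix.mtx"), stacked, field="integer")
    pd.Series(counts.barcodes).to_csv(out / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    feats = pd.DataFrame({
        "id": list(counts.gene_names) + list(counts.adt_names)
              + list(counts.hto_names),
        "name": list(counts.gene_names) + list(counts.adt_names)
                + list(counts.hto_names),
        "modality": [GENE_EXPRESSION] * len(counts.gene_names)
                    + [ANTIBODY_CAPTURE] * len(counts.adt_names)
                    + [HASHTAG] * len(counts.hto_names),
    })
    feats.to_csv(out / "features.tsv", sep="\t", index=False, header=False)


def read_multimodal(in_dir: str | Path) -> MultiModalCounts:
    """Read a triplet directory back into aligned per-modality matrices.

    Raises on dimension mismatches between the matrix and the TSVs, on a
    missing modality column, and on negative entries.
    """
    d = Path(in_dir)
    for fname in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (d / fname).exists():
            raise FileNotFoundError(f"{fname} not found in {d}")
    mat = sp.csr_matrix(scipy.io.mmread(str(d / "matrix.mtx")))
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0]
    feats = pd.read_csv(d / "features.tsv", sep="\t", header=None)
    if feats.shape[1] < 3:
        raise ValueError(
            "features.tsv lacks the third (modality) column; expected "
            "columns id, name, modality")
    feats.columns = ["id", "name", "modality"][: feats.shape[1]]
    if mat.shape != (len(feats), len(barcodes)):
        raise ValueError(
            f"matrix.mtx is {mat.shape} but features.tsv has {len(feats)} "
            f"rows and barcodes.tsv has {len(barcodes)} rows")
    unknown = set(feats["modality"]) - set(_MODALITIES)
    if unknown:
        raise ValueError(f"unknown feature type(s): {sorted(unknown)}; "
                         f"expected one of {_MODALITIES}")
    if mat.nnz and mat.data.min() < 0:
        raise ValueError("matrix.mtx contains negative entries")

    parts = {}
    names = {}
    for modality in _MODALITIES:
        mask = (feats["modality"] == modality).to_numpy()
        parts[modality] = mat[np.flatnonzero(mask), :]
        names[modality] = feats.loc[mask, "name"].tolist()
    return MultiModalCounts(
        barcodes=pd.Index(barcodes), rna=parts[GENE_EXPRESSION],
        adt=parts[ANTIBODY_CAPTURE], hto=parts[HASHTAG],
        gene_names=names[GENE_EXPRESSION], adt_names=names[ANTIBODY_CAPTURE],
        hto_names=names[HASHTAG])


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list.

    Lines starting with ``#`` are comments; duplicates are dropped (keeping
    first occurrence) with a warning; an empty list is an error.
    """
    seen: dict[str, None] = {}
    n_dups = 0
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if not sym or sym.startswith("#"):
            continue
        if sym in seen:
            n_dups += 1
        else:
            seen[sym] = None
    if n_dups:
        log.warning("gene list %s: dropped %d duplicated symbol(s)",
                    path, n_dups)
    if not seen:
        raise ValueError(f"gene list {path} is empty")
    return list(seen)
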