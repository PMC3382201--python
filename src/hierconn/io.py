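"""Reading and writing cohorts, matrices, ROI tables, and hierarchy trees.

All formats are plain text: delimited numeric matrices (one file per
subject), TSV ROI tables (1-based index, name, hemisphere), TSV edge lists,
Newick for cluster trees, and a YAML manifest tying a cohort directory
together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from hierconn.tree import ClusterNode, ClusterTree

logger = logging.getLogger(__name__)

#: relative tolerance below which an asymmetric input matrix is symmetrized
SYMMETRY_RTOL = 1e-9


class MatrixFormatError(ValueError):
    """Raised for non-square, negative, NaN, or asymmetric matrix input."""


def _validate_matrix(w: np.ndarray, *, context: str = "matrix") -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise MatrixFormatError(f"{context}: expected a square matrix, got shape {w.shape}")
    if np.isnan(w).any():
        raise MatrixFormatError(f"{context}: NaN entries are not allowed")
    if (w < 0).any():
        raise MatrixFormatError(f"{context}: negative weights are not allowed")
    scale = max(1.0, float(np.abs(w).max(initial=0.0)))
    asym = float(np.abs(w - w.T).max(initial=0.0))
    if asym > SYMMETRY_RTOL * scale:
        raise MatrixFormatError(
            f"{context}: asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_RTOL * scale:.3g}"
        )
    w = (w + w.T) / 2.0
    if np.diagonal(w).any():
        logger.warning("%s: nonzero diagonal forced to zero", context)
        np.fill_diagonal(w, 0.0)
    return w


@dataclass
class SubjectStack:
    """A cohort of symmetric non-negative connectivity matrices.

    Attributes
    ----------
    matrices
        Array of shape (S, N, N); each slice is one subject's symmetric,
        zero-diagonal, non-negative connectivity matrix.
    roi_labels
        N region names, in matrix row order.
    subject_ids
        S subject identifiers.
    """

    matrices: np.ndarray
    roi_labels: list[str]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        mats = np.asarray(self.matrices, dtype=float)
        if mats.ndim != 3:
            raise MatrixFormatError("matrices must be a (S, N, N) array")
        self.matrices = np.stack(
            [_validate_matrix(m, context=f"subject {i}") for i, m in enumerate(mats)]
        )
        n = self.matrices.shape[2]
        self.roi_labels = [str(x) for x in self.roi_labels]
        if len(self.roi_labels) != n:
            raise ValueError(f"{len(self.roi_labels)} labels for {n} nodes")
        if not self.subject_ids:
            self.subject_ids = [f"subj{i + 1:02d}" for i in range(len(self.matrices))]
        if len(self.subject_ids) != len(self.matrices):
            raise ValueError("subject_ids length does not match number of matrices")

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[2]

    def average(self) -> np.ndarray:
        """Entrywise mean over subjects (the group connectivity matrix)."""
        return self.matrices.mean(axis=0)


@dataclass
class ROITable:
    """Region-of-interest table: 1-based index, name, hemisphere."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"index", "name", "hemisphere"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ROI table missing columns: {sorted(missing)}")
        idx = self.table["index"].to_numpy()
        if len(set(idx)) != len(idx) or sorted(idx) != list(range(1, len(idx) + 1)):
            raise ValueError("ROI indices must be unique and contiguous from 1")
        bad = set(self.table["hemisphere"]) - {"left", "right", "none"}
        if bad:
            raise ValueError(f"unknown hemisphere values: {sorted(bad)}")

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "ROITable":
        """Build a table from names, inferring hemisphere from _L/_R suffixes."""
        hemi = [
            "left" if s.endswith("_L") else "right" if s.endswith("_R") else "none"
            for s in labels
        ]
        return cls(
            pd.DataFrame(
                {"index": range(1, len(labels) + 1), "name": list(labels), "hemisphere": hemi}
            )
        )


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a symmetric connectivity matrix from delimited text.

    Comma- or whitespace-delimited numeric text is accepted. The matrix is
    validated (square, non-negative, no NaN), symmetrized by averaging if the
    asymmetry is within ``SYMMETRY_RTOL`` (relative), and its diagonal forced
    to zero with a logged warning if nonzero.
    """
    path = Path(path)
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        w = np.loadtxt(str(path), delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: cannot parse numeric matrix: {exc}") from exc
    return _validate_matrix(w, context=str(path))


def write_matrix(w: np.ndarray, path: str | Path) -> None:
    """Write a matrix as tab-delimited text with full round-trip precision."""
    np.savetxt(str(path), np.asarray(w, dtype=float), fmt="%.17g", delimiter="\t")


def write_edge_list(w: np.ndarray, path: str | Path) -> None:
    """Write the upper triangle as a TSV edge list (1-based, i < j, w > 0)."""
    w = _validate_matrix(w, context=str(path))
    i, j = np.triu_indices(w.shape[0], k=1)
    keep = w[i, j] > 0
    df = pd.DataFrame(
        {"node_i": i[keep] + 1, "node_j": j[keep] + 1, "weight": w[i, j][keep]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_roi_table(path: str | Path) -> ROITable:
    return ROITable(pd.read_csv(path, sep="\t"))


def write_roi_table(table: ROITable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def filter_rois(
    stack: SubjectStack, roi_table: ROITable, exclude_names: Iterable[str]
) -> SubjectStack:
    """Restrict a cohort to the ROIs not listed in ``exclude_names``.

    Row/column order of the retained ROIs is preserved. Unknown names raise.
    """
    exclude = list(exclude_names)
    known = set(roi_table.names)
    unknown = [name for name in exclude if name not in known]
    if unknown:
        raise ValueError(f"unknown ROI names: {unknown}")
    if len(roi_table.names) != stack.n_nodes:
        raise ValueError("ROI table size does not match stack")
    excluded = set(exclude)
    keep_idx = [i for i, name in enumerate(roi_table.names) if name not in excluded]
    sub = stack.matrices[:, keep_idx, :][:, :, keep_idx]
    return SubjectStack(
        sub,
        [stack.roi_labels[i] for i in keep_idx],
        list(stack.subject_ids),
    )


# ---------------------------------------------------------------------------
# Newick export of cluster trees


def tree_to_newick(
    tree: ClusterTree,
    roi_labels: Sequence[str] | None = None,
    *,
    branch_lengths: bool = False,
) -> str:
    """Serialize a cluster tree as a Newick string.

    Leaf names are the cluster's member labels joined by ``|``; internal
    nodes are unlabeled. With ``branch_lengths=True`` every edge gets
    length 1 (one tier per level).
    """
    if not tree.root.members:
        raise ValueError("cannot serialize an empty tree")

    def name(node: ClusterNode) -> str:
        if roi_labels is not None:
            return "|".join(roi_labels[i] for i in node.members)
        return "|".join(str(i + 1) for i in node.members)

    def render(node: ClusterNode) -> str:
        suffix = ":1" if branch_lengths else ""
        if node.is_leaf():
            label = name(node)
            # multi-member leaf clusters are displayed as a parenthesized group
            if len(node.members) > 1 and node.parent is not None:
                return f"({label})" + suffix
            return label + suffix
        inner = ",".join(render(c) for c in node.children)
        return f"({inner})" + ("" if node.parent is None else suffix)

    return render(tree.root) + ";"


def write_tree_newick(
    tree: ClusterTree,
    roi_labels: Sequence[str] | None,
    path: str | Path,
    *,
    branch_lengths: bool = False,
) -> None:
    Path(path).write_text(tree_to_newick(tree, roi_labels, branch_lengths=branch_lengths) + "\n")


# ---------------------------------------------------------------------------
# Cohort directories


def write_cohort(stack: SubjectStack, directory: str | Path, *, manifest_extra: dict | None = None) -> None:
    """Write a cohort as one matrix file per subject plus ROI table and manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, mat in zip(stack.subject_ids, stack.matrices):
        write_matrix(mat, directory / f"{sid}.tsv")
    write_roi_table(ROITable.from_labels(stack.roi_labels), directory / "rois.tsv")
    manifest = {"subjects": list(stack.subject_ids), "n_nodes": stack.n_nodes}
    if manifest_extra:
        manifest.update(manifest_extra)
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_cohort(directory: str | Path) -> SubjectStack:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    subjects = manifest["subjects"]
    mats = np.stack([read_matrix(directory / f"{sid}.tsv") for sid in subjects])
    labels = read_roi_table(directory / "rois.tsv").names
    return SubjectStack(mats, labels, list(subjects))
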