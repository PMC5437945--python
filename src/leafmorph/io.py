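"""Readers and writers for leaf-morphometric data.

Supported formats:

* landmark tables — wide CSV (one row per leaf with ``x1..x15, y1..y15``
  columns) or long TSV (one row per landmark), both with leaf metadata;
* NEF normalized elliptical Fourier files — a plain-text dialect with one id
  line per specimen followed by ``n_harmonics`` lines of four whitespace
  separated coefficients (A B C D), ``#`` comment lines ignored, optionally
  tolerating a leading per-specimen harmonic-count line;
* binary leaf masks (PNG/BMP/...), with polarity auto-detection and
  single-component validation.

Node numbering: raw leaf scans count nodes from the growing tip (youngest
leaf = 1), while the heteroblastic series counts from the shoot base (first
emerged leaf = 1).  Tables are stored base-1-at-the-shoot-base internally;
:func:`convert_node_numbering` converts at ingest and is its own inverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LeafRecord",
    "LandmarkTable",
    "NEFFile",
    "TableDialect",
    "read_landmark_table",
    "write_landmark_table",
    "read_nef",
    "write_nef",
    "load_binary_mask",
    "convert_node_numbering",
]

N_LANDMARKS = 15
SPECIES_CLASSES = tuple("ABCDEFG")


@dataclass
class LeafRecord:
    """Metadata for one leaf: identity, replication, and node position."""

    leaf_id: str
    species: str = "unknown"
    species_class: str = "unknown"
    vine_id: str = "unknown"
    node_base1: int = 1
    node_tip1: int | None = None

    def __post_init__(self) -> None:
        if self.node_base1 < 1:
            raise ValueError(f"leaf {self.leaf_id}: node_base1 must be >= 1")
        if self.node_tip1 is not None and self.node_tip1 < 1:
            raise ValueError(f"leaf {self.leaf_id}: node_tip1 must be >= 1")
        if self.species_class not in SPECIES_CLASSES and self.species_class != "unknown":
            raise ValueError(
                f"leaf {self.leaf_id}: species_class must be one of "
                f"{SPECIES_CLASSES} or 'unknown', got {self.species_class!r}"
            )


@dataclass
class LandmarkTable:
    """Leaf metadata plus one 15-point configuration per leaf."""

    records: list[LeafRecord]
    configurations: np.ndarray  # (n, 15, 2)

    def __post_init__(self) -> None:
        self.configurations = np.asarray(self.configurations, dtype=float)
        if self.configurations.ndim != 3 or self.configurations.shape[1:] != (N_LANDMARKS, 2):
            raise ValueError(f"configurations must be (n, {N_LANDMARKS}, 2)")
        if len(self.records) != self.configurations.shape[0]:
            raise ValueError("records and configurations must align 1:1")
        if not np.all(np.isfinite(self.configurations)):
            raise ValueError("non-finite landmark coordinate")

    def __len__(self) -> int:
        return len(self.records)

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "leaf_id": [r.leaf_id for r in self.records],
                "species": [r.species for r in self.records],
                "species_class": [r.species_class for r in self.records],
                "vine_id": [r.vine_id for r in self.records],
                "node_base1": [r.node_base1 for r in self.records],
            }
        ).set_index("leaf_id")

    def coordinate_frame(self) -> pd.DataFrame:
        """Wide trait layout: columns x1..x15, y1..y15, indexed by leaf id."""
        n = self.configurations.shape[0]
        flat = np.concatenate(
            [self.configurations[:, :, 0], self.configurations[:, :, 1]], axis=1
        )
        cols = [f"x{i}" for i in range(1, N_LANDMARKS + 1)] + [
            f"y{i}" for i in range(1, N_LANDMARKS + 1)
        ]
        return pd.DataFrame(flat, index=[r.leaf_id for r in self.records], columns=cols)


@dataclass
class TableDialect:
    """Declares the landmark-table layout; no sniffing is attempted."""

    layout: str = "wide"        # "wide" or "long"
    sep: str = ","
    leaf_id: str = "leaf_id"
    species: str = "species"
    species_class: str = "species_class"
    vine_id: str = "vine_id"
    node: str = "node_base1"
    node_numbering: str = "base1"   # "base1" or "tip1"
    landmark_index: str = "landmark"  # long layout only
    x: str = "x"
    y: str = "y"

    def __post_init__(self) -> None:
        if self.layout not in ("wide", "long"):
            raise ValueError("layout must be 'wide' or 'long'")
        if self.node_numbering not in ("base1", "tip1"):
            raise ValueError("node_numbering must be 'base1' or 'tip1'")


def convert_node_numbering(node_tip1: int, nodes_on_vine: int) -> int:
    """Reverse node numbering between tip-1 (scan order) and base-1 (analysis).

    ``node_base1 = nodes_on_vine - node_tip1 + 1``; applying the conversion
    twice returns the input.
    """
    if not 1 <= node_tip1 <= nodes_on_vine:
        raise ValueError(
            f"node {node_tip1} outside valid range 1..{nodes_on_vine}"
        )
    return nodes_on_vine - node_tip1 + 1


def _record_from_row(row: pd.Series, d: TableDialect, leaf_id: str) -> LeafRecord:
    return LeafRecord(
        leaf_id=str(leaf_id),
        species=str(row.get(d.species, "unknown")),
        species_class=str(row.get(d.species_class, "unknown")),
        vine_id=str(row.get(d.vine_id, "unknown")),
        node_base1=int(row.get(d.node, 1)),
    )


def read_landmark_table(path, dialect: TableDialect | None = None) -> LandmarkTable:
    """Read a landmark table in the declared dialect.

    Rows with missing landmarks are excluded and reported via a warning in
    the wide layout; in the long layout a leaf with a landmark count other
    than 15 raises a validation error naming the leaf.
    """
    import warnings

    d = dialect or TableDialect()
    df = pd.read_csv(path, sep=d.sep)
    if d.leaf_id not in df.columns:
        raise ValueError(f"missing leaf id column {d.leaf_id!r}")

    records: list[LeafRecord] = []
    configs: list[np.ndarray] = []

    if d.layout == "wide":
        xcols = [f"x{i}" for i in range(1, N_LANDMARKS + 1)]
        ycols = [f"y{i}" for i in range(1, N_LANDMARKS + 1)]
        missing_cols = [c for c in xcols + ycols if c not in df.columns]
        if missing_cols:
            raise ValueError(f"wide layout missing coordinate columns: {missing_cols}")
        dropped = []
        for _, row in df.iterrows():
            coords = row[xcols + ycols].to_numpy(dtype=float)
            if not np.all(np.isfinite(coords)):
                dropped.append(str(row[d.leaf_id]))
                continue
            records.append(_record_from_row(row, d, row[d.leaf_id]))
            configs.append(np.column_stack([coords[:N_LANDMARKS], coords[N_LANDMARKS:]]))
        if dropped:
            warnings.warn(f"excluded {len(dropped)} leaves with missing landmarks: {dropped}")
    else:
        for col in (d.landmark_index, d.x, d.y):
            if col not in df.columns:
                raise ValueError(f"long layout missing column {col!r}")
        for leaf_id, grp in df.groupby(d.leaf_id, sort=False):
            if len(grp) != N_LANDMARKS:
                raise ValueError(
                    f"leaf {leaf_id!r} has {len(grp)} landmark rows, expected {N_LANDMARKS}"
                )
            grp = grp.sort_values(d.landmark_index)
            idx = grp[d.landmark_index].to_numpy()
            if not np.array_equal(idx, np.arange(1, N_LANDMARKS + 1)):
                raise ValueError(f"leaf {leaf_id!r}: landmark indices must be 1..{N_LANDMARKS}")
            coords = grp[[d.x, d.y]].to_numpy(dtype=float)
            if not np.all(np.isfinite(coords)):
                raise ValueError(f"leaf {leaf_id!r}: non-finite coordinate")
            records.append(_record_from_row(grp.iloc[0], d, leaf_id))
            configs.append(coords)

    if not records:
        raise ValueError("no complete leaves in table")

    if d.node_numbering == "tip1":
        by_vine: dict[str, int] = {}
        for r in records:
            by_vine[r.vine_id] = max(by_vine.get(r.vine_id, 0), r.node_base1)
        for r in records:
            r.node_tip1 = r.node_base1
            r.node_base1 = convert_node_numbering(r.node_tip1, by_vine[r.vine_id])

    return LandmarkTable(records=records, configurations=np.stack(configs))


def write_landmark_table(table: LandmarkTable, path) -> None:
    """Write the wide-CSV layout (metadata + x1..y15)."""
    out = pd.concat([table.metadata(), table.coordinate_frame()], axis=1)
    out.to_csv(path, index_label="leaf_id")


@dataclass
class NEFFile:
    """Normalized elliptical Fourier coefficients for a set of specimens."""

    specimen_ids: list[str]
    harmonics: np.ndarray  # (n_specimens, n_harmonics, 4) in A, B, C, D order

    def __post_init__(self) -> None:
        self.harmonics = np.asarray(self.harmonics, dtype=float)
        if self.harmonics.ndim != 3 or self.harmonics.shape[2] != 4:
            raise ValueError("harmonics must be (n_specimens, n_harmonics, 4)")
        if len(self.specimen_ids) != self.harmonics.shape[0]:
            raise ValueError("specimen ids and harmonics must align")
        if not np.all(np.isfinite(self.harmonics)):
            raise ValueError("non-finite harmonic coefficient")

    @property
    def n_harmonics(self) -> int:
        return self.harmonics.shape[1]

    def trait_frame(self) -> pd.DataFrame:
        """Trait layout A1..An, B1..Bn, C1..Cn, D1..Dn, indexed by specimen id."""
        n = self.n_harmonics
        cols = [f"{ltr}{k}" for ltr in "ABCD" for k in range(1, n + 1)]
        flat = np.concatenate([self.harmonics[:, :, j] for j in range(4)], axis=1)
        return pd.DataFrame(flat, index=self.specimen_ids, columns=cols)


def _is_float_row(tokens: list[str]) -> bool:
    if len(tokens) != 4:
        return False
    try:
        [float(t) for t in tokens]
        return True
    except ValueError:
        return False


def read_nef(path, allow_count_line: bool = True) -> NEFFile:
    """Parse a NEF text file.

    Record structure: one specimen-id line, then ``n_harmonics`` lines of four
    whitespace-separated reals (A B C D).  Lines starting with ``#`` are
    ignored.  If ``allow_count_line`` a single leading integer line per
    specimen (a harmonic count) is tolerated and checked.
    """
    text = Path(path).read_text()
    ids: list[str] = []
    blocks: list[list[list[float]]] = []
    pending_count: int | None = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if _is_float_row(tokens):
            if not ids:
                raise ValueError(f"line {lineno}: coefficient row before any specimen id")
            try:
                blocks[-1].append([float(t) for t in tokens])
            except ValueError as exc:  # pragma: no cover - guarded by _is_float_row
                raise ValueError(f"line {lineno}: non-numeric coefficient") from exc
        elif allow_count_line and len(tokens) == 1 and tokens[0].isdigit() and ids and not blocks[-1]:
            pending_count = int(tokens[0])
        else:
            if len(tokens) > 1 and not _is_float_row(tokens):
                # a line with several tokens that is not a coefficient row:
                # treat as parse error if it looks numeric
                if any(_looks_numeric(t) for t in tokens):
                    raise ValueError(
                        f"line {lineno}: expected 4 numeric coefficients, got {len(tokens)} tokens"
                    )
            if ids and pending_count is not None and len(blocks[-1]) != pending_count:
                raise ValueError(
                    f"specimen {ids[-1]!r}: declared {pending_count} harmonics, "
                    f"found {len(blocks[-1])}"
                )
            ids.append(line)
            blocks.append([])
            pending_count = None

    if not ids:
        raise ValueError("no specimens in NEF file")
    counts = {len(b) for b in blocks}
    if len(counts) != 1:
        detail = {i: len(b) for i, b in zip(ids, blocks)}
        raise ValueError(f"ragged harmonic counts across specimens: {detail}")
    n = counts.pop()
    if n == 0:
        raise ValueError("specimens contain no harmonic rows")
    return NEFFile(specimen_ids=ids, harmonics=np.array(blocks, dtype=float))


def _looks_numeric(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_nef(nef: NEFFile, path) -> None:
    """Write the NEF dialect; coefficients are formatted losslessly (%.17g)."""
    with open(path, "w") as fh:
        for sid, block in zip(nef.specimen_ids, nef.harmonics):
            fh.write(f"{sid}\n")
            for row in block:
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def load_binary_mask(
    path,
    threshold: float | None = None,
    foreground: str = "auto",
    single_leaf: bool = True,
) -> np.ndarray:
    """Load an image as a boolean leaf mask.

    ``threshold`` is on the 0..1 grayscale scale (default: midpoint 0.5).
    ``foreground`` is ``"auto"`` (the minority class), ``"light"`` or
    ``"dark"``.  With ``single_leaf`` the mask must contain exactly one
    8-connected foreground component.
    """
    from PIL import Image
    from scipy import ndimage

    img = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    thr = 0.5 if threshold is None else threshold
    light = img >= thr
    if foreground == "light":
        mask = light
    elif foreground == "dark":
        mask = ~light
    elif foreground == "auto":
        mask = light if light.sum() <= (~light).sum() else ~light
    else:
        raise ValueError("foreground must be 'auto', 'light' or 'dark'")

    if not mask.any():
        raise ValueError("empty foreground: no pixels above/below threshold")
    if single_leaf:
        labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n_comp != 1:
            sizes = sorted(np.bincount(labels.ravel())[1:].tolist(), reverse=True)
            raise ValueError(
                f"mask has {n_comp} connected components (sizes {sizes}); expected one leaf"
            )
    return mask
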