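"""Plain-text readers and writers: innervation tables, adjacency
matrices, hit maps and the subunit manifest.

Innervation tables are TSV with one row per neuron type and columns
``name, class, role, atypical`` followed by one code column per
subunit, headed by the subunit labels in canonical order, so a
write-then-read round trip is bit-exact.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectionMatrix
from .propagation import HitMap
from .space import Network, NeuronType, SubunitSpace, VALID_CODES, build_canonical_space

_META_COLUMNS = ["name", "class", "role", "atypical"]


def write_innervation_table(net: Network, path: str | Path) -> None:
    rows = []
    for t in net.types:
        rows.append(
            [t.name, t.class_name, t.role, int(t.atypical)] + [int(v) for v in t.vector]
        )
    frame = pd.DataFrame(rows, columns=_META_COLUMNS + list(net.space.labels))
    frame.to_csv(path, sep="\t", index=False)


def load_innervation_table(path: str | Path, space: SubunitSpace | None = None) -> Network:
    """Parse a TSV innervation table against a subunit space.

    The code columns must match the space's labels exactly (same set,
    same order); mismatches are reported label by label.  Codes outside
    {0,1,2,3} are rejected.
    """
    space = space or build_canonical_space()
    frame = pd.read_csv(path, sep="\t", dtype={"name": str, "class": str, "role": str})
    missing_meta = [c for c in _META_COLUMNS if c not in frame.columns]
    if missing_meta:
        raise ValueError(f"innervation table lacks columns {missing_meta}")
    code_cols = [c for c in frame.columns if c not in _META_COLUMNS]
    expected = list(space.labels)
    if code_cols != expected:
        unknown = sorted(set(code_cols) - set(expected))
        absent = sorted(set(expected) - set(code_cols))
        raise ValueError(
            f"subunit columns do not match the manifest: unknown={unknown[:5]}"
            f"{'...' if len(unknown) > 5 else ''}, absent={absent[:5]}"
            f"{'...' if len(absent) > 5 else ''}"
        )
    codes = frame[code_cols].to_numpy(dtype=np.int64)
    bad = set(np.unique(codes)) - set(VALID_CODES)
    if bad:
        raise ValueError(f"invalid innervation codes in table: {sorted(bad)}")

    types = []
    for row, vec in zip(frame.itertuples(index=False), codes):
        class_name = row[1]
        name = row[0]
        if not name.startswith(class_name):
            raise ValueError(f"type name {name!r} does not extend class {class_name!r}")
        index = int(name[len(class_name):])
        types.append(NeuronType(class_name, index, vec, atypical=bool(row[3])))
    return Network(space, types)


def write_adjacency(C: ConnectionMatrix, path: str | Path) -> None:
    C.to_frame().to_csv(path, sep="\t")


def load_adjacency(path: str | Path, classes: dict[str, str] | None = None) -> ConnectionMatrix:
    """Read a TSV adjacency matrix (types as header row and column).

    ``classes`` maps type names to class names; by default the class is
    the name stripped of its trailing type index.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError("adjacency row and column names differ")
    names = [str(n) for n in frame.index]
    if classes is None:
        classes = {n: n.rstrip("0123456789") for n in names}
    A = frame.to_numpy(dtype=np.int64)
    return ConnectionMatrix(
        names=names,
        classes=[classes[n] for n in names],
        A=A,
        weighted=bool((A > 1).any()),
    )


def write_hitmap(hm: HitMap, path: str | Path) -> None:
    frame = pd.DataFrame(
        {"subunit": list(hm.space.labels), "hits": [int(h) for h in hm.hits]}
    )
    frame.to_csv(path, sep="\t", index=False)


def write_manifest(space: SubunitSpace, path: str | Path) -> None:
    lines = [f"# subunit manifest: {space.size} subunits, block order fixed"]
    for b in space.blocks:
        lines.append(f"# {b.name} ({b.size})")
        lines.extend(b.labels)
    Path(path).write_text("\n".join(lines) + "\n")


def load_manifest_labels(path: str | Path | None = None) -> list[str]:
    """Subunit labels from a manifest file (default: the packaged
    canonical manifest)."""
    if path is None:
        text = resources.files("cxcircuit.data").joinpath("subunit_manifest.txt").read_text()
    else:
        text = Path(path).read_text()
    return [l for l in text.splitlines() if l and not l.startswith("#")]
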