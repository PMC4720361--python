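"""Readers and writers: species matrices (CSV), landscape specs (YAML/JSON)
and burn models (JSON)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import yaml

from .burn import BurnModel, BurnPattern, SizeDistribution
from .landscape import (GridLandscape, HexLandscape, LandscapeError,
                        build_hex_landscape, build_square_landscape,
                        hex_landscape_from_adjacency)
from .synthetic import SpeciesMatrix, SpeciesMatrixError

__all__ = [
    "read_species_matrix",
    "write_species_matrix",
    "species_summary",
    "load_landscape_spec",
    "landscape_to_spec",
    "burn_model_to_dict",
    "burn_model_from_dict",
    "write_burn_model",
    "read_burn_model",
]


def read_species_matrix(path: Union[str, Path], *,
                        delimiter: Optional[str] = None) -> SpeciesMatrix:
    """Read a parcel x species presence/absence CSV.

    First column: 1-based parcel id; remaining columns: one species each
    with 0/1 cells.  A header row is detected automatically; whitespace
    delimited matrices are accepted too.  Non-binary cells, ragged rows
    and duplicate parcel ids are rejected with the offending coordinates.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise SpeciesMatrixError(f"{path}: empty file")
    lines = text.splitlines()
    if delimiter is None:
        delimiter = "," if "," in lines[0] else None  # None -> whitespace split
    rows = [([tok.strip() for tok in ln.split(delimiter)] if delimiter
             else ln.split()) for ln in lines if ln.strip()]

    def _is_int(tok: str) -> bool:
        try:
            int(tok)
            return True
        except ValueError:
            return False

    header: Optional[List[str]] = None
    if not all(_is_int(t) for t in rows[0]):
        header = rows[0]
        rows = rows[1:]
    if not rows:
        raise SpeciesMatrixError(f"{path}: no data rows")
    width = len(rows[0])
    parcel_ids: List[int] = []
    data: List[List[int]] = []
    for rnum, row in enumerate(rows, start=2 if header else 1):
        if len(row) != width:
            raise SpeciesMatrixError(
                f"{path}: ragged row {rnum} has {len(row)} fields, expected {width}")
        if not _is_int(row[0]):
            raise SpeciesMatrixError(f"{path}: row {rnum} parcel id {row[0]!r}")
        parcel_ids.append(int(row[0]))
        vals = []
        for cnum, tok in enumerate(row[1:], start=2):
            if tok not in ("0", "1"):
                raise SpeciesMatrixError(
                    f"{path}: non-binary cell at row {rnum}, column {cnum}: {tok!r}")
            vals.append(int(tok))
        data.append(vals)
    if len(set(parcel_ids)) != len(parcel_ids):
        dup = next(p for p in parcel_ids if parcel_ids.count(p) > 1)
        raise SpeciesMatrixError(f"{path}: duplicate parcel id {dup}")
    species_ids = tuple(header[1:]) if header else tuple(
        f"sp{i + 1}" for i in range(width - 1))
    return SpeciesMatrix(presence=np.array(data, dtype=np.int8),
                         parcel_ids=tuple(parcel_ids), species_ids=species_ids)


def write_species_matrix(species: SpeciesMatrix, path: Union[str, Path]) -> None:
    """Inverse of :func:`read_species_matrix` (CSV with a header row)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("parcel," + ",".join(species.species_ids) + "\n")
        for pid, row in zip(species.parcel_ids, species.presence):
            fh.write(str(pid) + "," + ",".join(str(int(v)) for v in row) + "\n")


def species_summary(species: SpeciesMatrix) -> Dict[str, float]:
    rich = species.richness()
    return {
        "n_parcels": int(species.n_parcels),
        "n_species": int(species.n_species),
        "richness_min": int(rich.min()),
        "richness_mean": float(rich.mean()),
        "richness_max": int(rich.max()),
    }


# -- landscape specs -----------------------------------------------------

def load_landscape_spec(source: Union[str, Path, Dict]):
    """Build a landscape from a YAML/JSON spec file or an equivalent dict.

    Accepted forms::

        {type: square, rows: 5, cols: 5, buffer_width: 1}
        {type: hex, rows: 17, cols: 17}
        {type: hex_explicit, n_parcels: 4, adjacency: [[1,2],[2,3],[3,4]]}
    """
    if isinstance(source, (str, Path)):
        spec = yaml.safe_load(Path(source).read_text())
    else:
        spec = dict(source)
    if not isinstance(spec, dict) or "type" not in spec:
        raise LandscapeError("landscape spec must be a mapping with a 'type' key")
    kind = spec["type"]
    if kind == "square":
        return build_square_landscape(int(spec["rows"]), int(spec["cols"]),
                                      int(spec.get("buffer_width", 1)))
    if kind == "hex":
        return build_hex_landscape(int(spec["rows"]), int(spec["cols"]))
    if kind == "hex_explicit":
        edges = [(int(a), int(b)) for a, b in spec["adjacency"]]
        return hex_landscape_from_adjacency(int(spec["n_parcels"]), edges)
    raise LandscapeError(f"unknown landscape type {kind!r}")


def landscape_to_spec(landscape) -> Dict:
    if isinstance(landscape, GridLandscape):
        return {"type": "square", "rows": landscape.rows, "cols": landscape.cols,
                "buffer_width": landscape.buffer_width}
    if isinstance(landscape, HexLandscape):
        edges = sorted({tuple(sorted((p, nb)))
                        for p in landscape.focal_ids
                        for nb in landscape.spread_neighbors(p)})
        return {"type": "hex_explicit", "n_parcels": landscape.n_parcels,
                "adjacency": [list(e) for e in edges]}
    raise LandscapeError(f"unknown landscape object {type(landscape)!r}")


# -- burn models ---------------------------------------------------------

def burn_model_to_dict(model: BurnModel) -> Dict:
    if model.is_closed_form:
        return {
            "kind": "independent_closed_form",
            "J": model.J,
            "size_distribution": {str(n): q for n, q in model.sizes.probs.items()},
        }
    return {
        "kind": model.kind,
        "representation": model.representation,
        "patterns": [
            {"ignitions": list(p.ignitions), "burned": sorted(p.burned),
             "probability": p.probability}
            for p in model.patterns
        ],
    }


def burn_model_from_dict(d: Dict) -> BurnModel:
    if d.get("kind") == "independent_closed_form":
        sizes = SizeDistribution(probs={int(n): float(q)
                                        for n, q in d["size_distribution"].items()})
        return BurnModel(kind="independent", representation="closed_form",
                         J=int(d["J"]), sizes=sizes)
    patterns = tuple(
        BurnPattern(burned=frozenset(int(b) for b in p["burned"]),
                    probability=float(p["probability"]),
                    ignitions=tuple(int(i) for i in p.get("ignitions", ())))
        for p in d["patterns"]
    )
    return BurnModel(kind=d["kind"], representation=d.get("representation", "enumerated"),
                     patterns=patterns)


def write_burn_model(model: BurnModel, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(burn_model_to_dict(model), indent=1))


def read_burn_model(path: Union[str, Path]) -> BurnModel:
    return burn_model_from_dict(json.loads(Path(path).read_text()))
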