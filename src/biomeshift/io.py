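"""File formats: tip data, constraints, configuration, and reports.

Tip data is delimited text, one row per species, one column per biome,
cells drawn from ``{0, 1, 2, 01, ?}`` where ``?`` is shorthand for the
worst-case ``01`` (enabled or non-affinity, unresolved).  Constraints are
rows of (species, biome, action) with action ``include`` or ``exclude``;
the climatic-adjacency gradient is declared in the run configuration as an
ordered biome list.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .states import (
    AdjacencyRule,
    ConstraintSet,
    StateSpace,
    TipAmbiguity,
    TipObservation,
    compatible_states,
)

__all__ = [
    "read_tip_data",
    "write_tip_data",
    "read_constraints",
    "read_config",
    "write_config",
    "write_state_report",
]

log = logging.getLogger("biomeshift")

_CELL_CODES = {
    "0": frozenset({0}),
    "1": frozenset({1}),
    "2": frozenset({2}),
    "01": frozenset({0, 1}),
    "?": frozenset({0, 1}),
}


def _biome_index(biome: str, space: StateSpace) -> int:
    if biome in space.biome_labels:
        return space.biome_labels.index(biome)
    try:
        idx = int(biome)
    except ValueError:
        raise ValueError(
            f"unknown biome {biome!r}; expected one of {space.biome_labels} "
            "or a 0-based index"
        ) from None
    if not (0 <= idx < space.n_biomes):
        raise ValueError(f"biome index {idx} out of range")
    return idx


def read_constraints(path: str | Path, space: StateSpace) -> ConstraintSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species", "biome", "action"}
    if not required <= set(df.columns):
        raise ValueError(f"constraint file needs columns {sorted(required)}")
    cs = ConstraintSet()
    for _, row in df.iterrows():
        target = (str(row["species"]), _biome_index(str(row["biome"]), space))
        action = str(row["action"]).strip().lower()
        if action == "include":
            cs.includes.add(target)
        elif action == "exclude":
            cs.excludes.add(target)
        else:
            raise ValueError(f"unknown constraint action {action!r}")
    if cs.includes & cs.excludes:
        raise ValueError("a (species, biome) pair is both included and excluded")
    return cs


def read_tip_data(
    path: str | Path,
    space: StateSpace,
    constraints_path: Optional[str | Path] = None,
    adjacency: Optional[AdjacencyRule] = None,
) -> list[TipAmbiguity]:
    """Parse tip observations and apply constraints into ambiguity masks."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "species":
        raise ValueError("first tip-data column must be 'species'")
    biome_cols = list(df.columns[1:])
    if tuple(biome_cols) != tuple(space.biome_labels):
        raise ValueError(
            f"tip-data biome columns {biome_cols} do not match the declared "
            f"biome order {list(space.biome_labels)}"
        )
    if df["species"].duplicated().any():
        dupes = df["species"][df["species"].duplicated()].tolist()
        raise ValueError(f"duplicate species rows: {dupes}")

    constraints = (
        read_constraints(constraints_path, space)
        if constraints_path is not None
        else ConstraintSet()
    )
    constraints.adjacency = adjacency
    known = set(df["species"])
    for sp, _ in constraints.includes | constraints.excludes:
        if sp not in known:
            raise ValueError(f"constraint names unknown species {sp!r}")

    masks = []
    n_established = n_ambiguous = 0
    for _, row in df.iterrows():
        allowed = []
        for col in biome_cols:
            cell = str(row[col]).strip()
            if cell not in _CELL_CODES:
                raise ValueError(
                    f"species {row['species']}: invalid cell {cell!r} "
                    f"(expected one of {sorted(_CELL_CODES)})"
                )
            allowed.append(_CELL_CODES[cell])
            n_established += cell == "2"
            n_ambiguous += cell in ("01", "?")
        obs = TipObservation(str(row["species"]), tuple(allowed))
        masks.append(compatible_states(obs, constraints, space))
    log.info(
        "read %d species: %d established cells, %d ambiguous cells, "
        "%d includes, %d excludes, adjacency=%s",
        len(masks), n_established, n_ambiguous,
        len(constraints.includes), len(constraints.excludes),
        "on" if adjacency else "off",
    )
    return masks


def write_tip_data(
    path: str | Path,
    species: Sequence[str],
    cells: Sequence[Sequence[str]],
    space: StateSpace,
) -> None:
    df = pd.DataFrame(cells, columns=list(space.biome_labels))
    df.insert(0, "species", list(species))
    df.to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def write_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_state_report(path: str | Path, space: StateSpace) -> None:
    space.report().to_csv(path, sep="\t", index=False)
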