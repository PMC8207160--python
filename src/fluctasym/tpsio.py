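"""Replicated 2-D landmark data: containers, TPS reading/writing, dataset assembly.

Landmark configurations are keyed by (specimen, side, image replicate,
digitizing replicate).  TPS files — the de-facto exchange format of 2-D
geometric morphometrics — carry no structured replicate fields, so replicate
information is parsed out of the ID string by a pluggable ``id_parser``.  The
default dialect is ``<specimen>_<side>_i<image>_d<digitizing>`` (for example
``MN1234_L_i1_d3``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "LandmarkDataset",
    "ReplicateDesign",
    "AssemblyReport",
    "default_id_parser",
    "read_tps",
    "write_tps",
    "assemble_dataset",
]

SIDES = ("left", "right")

_SIDE_ALIASES = {
    "l": "left",
    "left": "left",
    "r": "right",
    "right": "right",
}


def normalize_side(side: str) -> str:
    try:
        return _SIDE_ALIASES[str(side).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown side label: {side!r} (expected left/right)") from None


@dataclass(frozen=True)
class ReplicateDesign:
    """Nominal replicate structure: images per side, digitizings per image."""

    n_images: int = 1
    n_digitizings: int = 1

    def __post_init__(self) -> None:
        if self.n_images < 1 or self.n_digitizings < 1:
            raise ValueError("replicate counts must be >= 1")


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One digitized landmark configuration (a single side of one specimen,
    from one image, one digitizing round)."""

    specimen_id: str
    side: str
    image_rep: int
    digit_rep: int
    coords: np.ndarray
    population: str = ""
    scale: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "side", normalize_side(self.side))
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be a k x 2 array")
        if not np.all(np.isfinite(coords)):
            raise ValueError(
                f"non-finite coordinates in configuration {self.key()}"
            )
        if self.image_rep < 1 or self.digit_rep < 1:
            raise ValueError("replicate indices must be >= 1")
        object.__setattr__(self, "coords", coords)

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def key(self) -> tuple[str, str, int, int]:
        return (self.specimen_id, self.side, self.image_rep, self.digit_rep)


class LandmarkDataset:
    """A validated collection of landmark configurations.

    Configurations are stored in canonical key order (sorted by specimen,
    side, image, digitizing), which makes downstream alignment independent of
    input order.
    """

    def __init__(
        self,
        configurations: Iterable[LandmarkConfiguration],
        design: ReplicateDesign | None = None,
    ):
        configs = sorted(configurations, key=lambda c: c.key())
        if not configs:
            raise ValueError("dataset must contain at least one configuration")
        ks = {c.k for c in configs}
        if len(ks) != 1:
            raise ValueError(f"inconsistent landmark counts across dataset: {sorted(ks)}")
        seen: dict[tuple, LandmarkConfiguration] = {}
        for c in configs:
            if c.key() in seen:
                raise ValueError(f"duplicate configuration key: {c.key()}")
            seen[c.key()] = c
        self.configurations: list[LandmarkConfiguration] = configs
        self._index = seen
        self.k: int = configs[0].k
        if design is None:
            design = ReplicateDesign(
                n_images=max(c.image_rep for c in configs),
                n_digitizings=max(c.digit_rep for c in configs),
            )
        self.design = design

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    def __getitem__(self, key: tuple[str, str, int, int]) -> LandmarkConfiguration:
        return self._index[key]

    def specimens(self) -> list[str]:
        return sorted({c.specimen_id for c in self.configurations})

    def sides_of(self, specimen_id: str) -> set[str]:
        return {c.side for c in self.configurations if c.specimen_id == specimen_id}

    def populations(self) -> dict[str, str]:
        return {c.specimen_id: c.population for c in self.configurations}

    def coords_array(self) -> np.ndarray:
        """All configurations stacked as an (n, k, 2) array, canonical order."""
        return np.stack([c.coords for c in self.configurations])

    def keys_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "specimen_id": [c.specimen_id for c in self.configurations],
                "population": [c.population for c in self.configurations],
                "side": [c.side for c in self.configurations],
                "image_rep": [c.image_rep for c in self.configurations],
                "digit_rep": [c.digit_rep for c in self.configurations],
            }
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table, one row per configuration x landmark."""
        rows = []
        for c in self.configurations:
            for j, (x, y) in enumerate(c.coords, start=1):
                rows.append(
                    (c.specimen_id, c.population, c.side, c.image_rep, c.digit_rep, j, x, y)
                )
        return pd.DataFrame(
            rows,
            columns=[
                "specimen_id", "population", "side", "image_rep",
                "digit_rep", "landmark", "x", "y",
            ],
        )

    def map_coords(self, fn: Callable[[LandmarkConfiguration], np.ndarray]) -> "LandmarkDataset":
        return LandmarkDataset(
            [replace(c, coords=fn(c)) for c in self.configurations], design=self.design
        )


_DEFAULT_ID_RE = re.compile(
    r"^(?P<specimen>.+?)[_\-](?P<side>[LlRr]|left|right|LEFT|RIGHT)"
    r"[_\-]i(?P<image>\d+)[_\-]d(?P<digit>\d+)$"
)


def default_id_parser(id_string: str) -> dict:
    """Parse ``<specimen>_<side>_i<image>_d<digit>`` ID strings."""
    m = _DEFAULT_ID_RE.match(id_string.strip())
    if m is None:
        raise ValueError(
            f"cannot parse ID {id_string!r}: expected '<specimen>_<L|R>_i<n>_d<m>'"
        )
    return {
        "specimen_id": m.group("specimen"),
        "side": normalize_side(m.group("side")),
        "image_rep": int(m.group("image")),
        "digit_rep": int(m.group("digit")),
    }


def read_tps(
    path,
    id_parser: Callable[[str], dict] = default_id_parser,
    population: str = "",
    y_down: bool = False,
) -> LandmarkDataset:
    """Read a TPS file into a :class:`LandmarkDataset`.

    Supports LM=, coordinate lines, ID=, IMAGE= and SCALE= records.  When a
    SCALE record is present the coordinates are multiplied by it (converting
    pixels to physical units).  ``y_down=True`` negates y on read for files
    digitized in image (y-down) convention.
    """
    records: list[LandmarkConfiguration] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]

    i = 0
    rec_no = 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise ValueError(f"{path}: expected LM= at line {i + 1}, got {line!r}")
        rec_no += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError:
            raise ValueError(f"{path}: bad LM count in record {rec_no}") from None
        i += 1
        coords = []
        while i < len(lines) and len(coords) < k:
            parts = lines[i].split()
            if len(parts) != 2:
                break
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError:
                break
            i += 1
        if len(coords) != k:
            raise ValueError(
                f"{path}: record {rec_no} declares LM={k} but has {len(coords)} coordinate lines"
            )
        id_string = None
        image = None
        scale = None
        while i < len(lines):
            ln = lines[i]
            up = ln.upper()
            if up.startswith("ID="):
                id_string = ln.split("=", 1)[1].strip()
            elif up.startswith("IMAGE="):
                image = ln.split("=", 1)[1].strip()
            elif up.startswith("SCALE="):
                scale = float(ln.split("=", 1)[1])
            elif up.startswith("LM=") or not ln:
                break
            i += 1
        if id_string is None and image is None:
            raise ValueError(f"{path}: record {rec_no} has neither ID= nor IMAGE=")
        try:
            fields = id_parser(id_string if id_string is not None else image)
        except ValueError as exc:
            raise ValueError(f"{path}: record {rec_no}: {exc}") from None
        arr = np.asarray(coords, dtype=float)
        if y_down:
            arr[:, 1] = -arr[:, 1]
        if scale is not None:
            arr = arr * scale
        records.append(
            LandmarkConfiguration(
                coords=arr, population=population, scale=scale, **fields
            )
        )
    return LandmarkDataset(records)


def write_tps(dataset: LandmarkDataset, path) -> None:
    """Write a dataset as TPS records with ``ID=<specimen>_<L|R>_i<n>_d<m>``.

    Coordinates are written with enough digits to round-trip through
    :func:`read_tps` to better than 1e-9.
    """
    with open(path, "w") as fh:
        for c in dataset.configurations:
            fh.write(f"LM={c.k}\n")
            for x, y in c.coords:
                fh.write(f"{x:.12g} {y:.12g}\n")
            side = "L" if c.side == "left" else "R"
            fh.write(f"ID={c.specimen_id}_{side}_i{c.image_rep}_d{c.digit_rep}\n")


@dataclass
class AssemblyReport:
    """Completeness report produced by :func:`assemble_dataset`."""

    complete: bool
    n_configurations: int
    excluded_specimens: list[str] = field(default_factory=list)
    missing_replicates: list[tuple] = field(default_factory=list)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        status = "complete" if self.complete else "incomplete"
        return (
            f"AssemblyReport({status}, {self.n_configurations} configurations, "
            f"{len(self.excluded_specimens)} specimens excluded, "
            f"{len(self.missing_replicates)} replicate slots missing)"
        )


def assemble_dataset(
    configs: Sequence[LandmarkConfiguration],
    design: ReplicateDesign,
) -> tuple[LandmarkDataset, AssemblyReport]:
    """Assemble configurations into a dataset and report completeness.

    Specimens missing an entire side cannot enter a matching-symmetry
    analysis; they are excluded from the returned dataset and listed in the
    report.  Missing replicate slots are tolerated (the ANOVA handles
    unbalanced designs) but logged.
    """
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise ValueError(f"mixed landmark counts: {sorted(ks)}")
    by_spec: dict[str, list[LandmarkConfiguration]] = {}
    for c in configs:
        by_spec.setdefault(c.specimen_id, []).append(c)

    excluded = []
    kept: list[LandmarkConfiguration] = []
    missing: list[tuple] = []
    for spec_id in sorted(by_spec):
        group = by_spec[spec_id]
        sides = {c.side for c in group}
        if sides != set(SIDES):
            excluded.append(spec_id)
            continue
        kept.extend(group)
        have = {(c.side, c.image_rep, c.digit_rep) for c in group}
        for side in SIDES:
            for i in range(1, design.n_images + 1):
                for d in range(1, design.n_digitizings + 1):
                    if (side, i, d) not in have:
                        missing.append((spec_id, side, i, d))
    dataset = LandmarkDataset(kept, design=design)
    report = AssemblyReport(
        complete=not excluded and not missing,
        n_configurations=len(kept),
        excluded_specimens=excluded,
        missing_replicates=missing,
    )
    return dataset, report
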