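"""Movement catalog: per-movement projection plane, zero reference, sign, cap.

The catalog ships as a declarative YAML file (``movements.yaml``) so that
planes, references and caps are data rather than code.  Sided movements
(shoulder, hip) are stored for the right side; :func:`spec_for` mirrors
them onto the left side by substituting joint names, negating the zero
reference's x component and flipping the sign for planes that contain x
(mirroring reverses in-plane orientation there; sagittal projections are
unaffected).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

PLANES = ("frontal", "sagittal", "transverse")

#: Retained coordinate indices per anatomical plane in the (x, y, z) body
#: frame; the dropped axis is the plane normal.
PLANE_AXES: dict[str, tuple[int, int]] = {
    "sagittal": (1, 2),
    "frontal": (0, 1),
    "transverse": (0, 2),
}

SHOULDER_MOVEMENTS = (
    "shoulder-ff",
    "shoulder-extension",
    "shoulder-abduction",
    "shoulder-adduction",
    "shoulder-abd90-er",
    "shoulder-abd90-ir",
    "shoulder-ff90-er",
    "shoulder-ff90-ir",
)
HIP_MOVEMENTS = ("hip-ff", "hip-extension", "hip-abduction", "hip-adduction")
SPINE_MOVEMENTS = (
    "spine-ff",
    "spine-extension",
    "spine-left-lateral",
    "spine-right-lateral",
)
ALL_MOVEMENTS = SHOULDER_MOVEMENTS + HIP_MOVEMENTS + SPINE_MOVEMENTS


@dataclass(frozen=True)
class MovementSpec:
    """Fully resolved definition of one movement on one side.

    ``positive_sign`` orients the signed in-plane angle so the movement's
    own direction reads positive; ``cap_degrees`` is the anatomical
    normal-range saturation applied to the final maximum (None = uncapped).
    """

    movement_id: str
    joint_group: str
    side: str  # "left" | "right" | "none"
    proximal_joint: str
    distal_joint: str
    plane: str
    zero_reference: tuple[float, float, float]
    positive_sign: int
    cap_degrees: float | None = None

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        if self.positive_sign not in (-1, 1):
            raise ValueError("positive_sign must be +1 or -1")
        z = np.asarray(self.zero_reference, float)
        if z.shape != (3,) or not np.isfinite(z).all() or np.linalg.norm(z) == 0:
            raise ValueError("zero_reference must be a finite nonzero 3-vector")

    @property
    def zero_reference_vec(self) -> np.ndarray:
        return np.asarray(self.zero_reference, float)


def _catalog_path() -> Path:
    return Path(str(resources.files("romagree").joinpath("movements.yaml")))


def load_catalog(path: str | Path | None = None) -> dict[str, dict]:
    """Load the raw catalog, keyed by movement_id."""
    p = Path(path) if path is not None else _catalog_path()
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    entries = {}
    for e in raw["movements"]:
        entries[e["movement_id"]] = e
    if len(entries) != 16:
        raise ValueError(f"catalog must define 16 movements, found {len(entries)}")
    return entries


_CATALOG_CACHE: dict[str, dict] | None = None


def _catalog() -> dict[str, dict]:
    global _CATALOG_CACHE
    if _CATALOG_CACHE is None:
        _CATALOG_CACHE = load_catalog()
    return _CATALOG_CACHE


def spec_for(
    movement_id: str, side: str = "none", catalog: dict[str, dict] | None = None
) -> MovementSpec:
    """Resolve a catalog entry to a concrete :class:`MovementSpec`.

    Sided movements require ``side`` in {"left", "right"}; axial (spine)
    movements require ``side="none"``.
    """
    cat = catalog if catalog is not None else _catalog()
    if movement_id not in cat:
        raise KeyError(f"movement {movement_id!r} is not in the catalog")
    e = cat[movement_id]
    sided = bool(e["sided"])
    if sided and side not in ("left", "right"):
        raise ValueError(f"{movement_id} is sided; side must be 'left' or 'right'")
    if not sided and side not in ("none", None):
        raise ValueError(f"{movement_id} is axial; side must be 'none'")

    zero = np.asarray(e["zero_reference"], float)
    sign = int(e["sign"])
    if sided and side == "left":
        zero = zero.copy()
        zero[0] = -zero[0]
        if e["plane"] in ("frontal", "transverse"):
            sign = -sign
    fmt = {"side": side} if sided else {}
    return MovementSpec(
        movement_id=movement_id,
        joint_group=e["joint_group"],
        side=side if sided else "none",
        proximal_joint=e["proximal"].format(**fmt),
        distal_joint=e["distal"].format(**fmt),
        plane=e["plane"],
        zero_reference=tuple(float(v) for v in zero),
        positive_sign=sign,
        cap_degrees=None if e["cap_degrees"] is None else float(e["cap_degrees"]),
    )


#: Axial movements that swap under a left-right mirror (frontal-plane
#: trunk movements); sagittal axial movements are their own mirror image.
_AXIAL_MIRROR_PAIRS = {
    "spine-left-lateral": "spine-right-lateral",
    "spine-right-lateral": "spine-left-lateral",
}


def mirrored_spec(spec: MovementSpec) -> MovementSpec:
    """The movement a left-right mirrored skeleton performs.

    Sided specs move to the opposite side; axial frontal-plane movements
    swap with their lateral counterpart; axial sagittal movements are
    unchanged.
    """
    if spec.side == "none":
        partner = _AXIAL_MIRROR_PAIRS.get(spec.movement_id, spec.movement_id)
        return spec_for(partner, "none")
    other = "left" if spec.side == "right" else "right"
    return spec_for(spec.movement_id, other)


def sides_for(movement_id: str, catalog: dict[str, dict] | None = None) -> tuple[str, ...]:
    cat = catalog if catalog is not None else _catalog()
    return ("left", "right") if cat[movement_id]["sided"] else ("none",)
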