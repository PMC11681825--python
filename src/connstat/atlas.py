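"""Cortical parcellation metadata.

The package operates on signals and connectivity matrices defined over the
68-region Desikan-Killiany gyral parcellation (34 regions per hemisphere,
left hemisphere at indices 0-33, right at 34-67, FreeSurfer ``aparc``
ordering within each hemisphere).  Each region carries a coarse lobe label
used only for descriptive subnetwork summaries; the grouping of gyri into
lobes is a reporting convention shipped with the package, not an anatomical
ground truth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["AtlasRegion", "load_atlas", "AtlasError", "HEMISPHERES", "LOBES"]

HEMISPHERES = ("left", "right")
LOBES = (
    "fronto-insular",
    "sensorimotor",
    "limbic",
    "temporal",
    "parietal",
    "occipital",
)

N_REGIONS = 68
N_PER_HEMISPHERE = 34


class AtlasError(ValueError):
    """Raised when atlas metadata violates the parcellation contract."""


@dataclass(frozen=True)
class AtlasRegion:
    """One cortical region of interest.

    Attributes
    ----------
    index : int
        Position in the canonical region ordering (0-67).
    name : str
        Region label, e.g. ``"lh.precentral"``.
    hemisphere : str
        ``"left"`` or ``"right"``.
    lobe : str
        One of :data:`LOBES`.
    """

    index: int
    name: str
    hemisphere: str
    lobe: str


def _builtin_path() -> Path:
    return Path(str(resources.files("connstat") / "data" / "desikan_killiany_68.tsv"))


def load_atlas(path: str | Path | None = None) -> list[AtlasRegion]:
    """Load atlas metadata from a tab-delimited file.

    Parameters
    ----------
    path : path or None
        TSV with columns ``index``, ``name``, ``hemisphere``, ``lobe``.
        ``None`` loads the packaged Desikan-Killiany table.

    Returns
    -------
    list of AtlasRegion
        Exactly 68 regions sorted by index, 34 per hemisphere, with unique
        names and every region assigned one lobe.

    Raises
    ------
    AtlasError
        If the file does not describe a valid 68-region parcellation.
    """
    p = _builtin_path() if path is None else Path(path)
    regions: list[AtlasRegion] = []
    with open(p, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"index", "name", "hemisphere", "lobe"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise AtlasError(f"atlas file must have columns {sorted(required)}")
        for row in reader:
            hemi = row["hemisphere"].strip()
            lobe = row["lobe"].strip()
            if hemi not in HEMISPHERES:
                raise AtlasError(f"unknown hemisphere token {hemi!r}")
            if lobe not in LOBES:
                raise AtlasError(f"unknown lobe token {lobe!r}")
            regions.append(
                AtlasRegion(int(row["index"]), row["name"].strip(), hemi, lobe)
            )
    regions.sort(key=lambda r: r.index)
    _validate(regions)
    return regions


def _validate(regions: list[AtlasRegion]) -> None:
    if len(regions) != N_REGIONS:
        raise AtlasError(f"expected {N_REGIONS} regions, got {len(regions)}")
    if [r.index for r in regions] != list(range(N_REGIONS)):
        raise AtlasError("region indices must be 0..67 with no gaps")
    names = [r.name for r in regions]
    if len(set(names)) != N_REGIONS:
        raise AtlasError("region names must be unique")
    for hemi in HEMISPHERES:
        n = sum(r.hemisphere == hemi for r in regions)
        if n != N_PER_HEMISPHERE:
            raise AtlasError(
                f"expected {N_PER_HEMISPHERE} {hemi}-hemisphere regions, got {n}"
            )
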