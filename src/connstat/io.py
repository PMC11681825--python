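"""Cohort tables and connectivity-bundle serialization.

A *cohort table* holds one row per subject with a categorical group column
and real-valued covariates (age, disease duration, levodopa-equivalent
daily dose, most-affected side, BMI, hormone levels, ...).  An *FC bundle*
is a directory holding one delimited text matrix per (subject, band) pair
plus a JSON manifest; matrices are written with 17 significant digits so
the decimal round-trip is bit exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "FCBundle",
    "read_cohort",
    "write_fc_bundle",
    "read_fc_bundle",
    "BundleIntegrityError",
]


class BundleIntegrityError(RuntimeError):
    """A bundle manifest references data that is absent or inconsistent."""


@dataclass
class CohortTable:
    """Typed subject table with a designated group factor.

    Attributes
    ----------
    table : pandas.DataFrame
        Indexed by ``subject_id``; contains a ``group`` column plus
        covariate columns.
    group_levels : list of str
        Group levels in a fixed order; the first level is the reference
        level for design matrices.
    """

    table: pd.DataFrame
    group_levels: list[str]

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def k(self) -> int:
        return len(self.group_levels)

    @property
    def subjects(self) -> list[str]:
        return list(self.table.index)

    def groups(self) -> pd.Series:
        return self.table["group"]

    def covariate_matrix(self, names: list[str]) -> np.ndarray:
        """Return an (N, len(names)) float matrix of covariate columns."""
        missing = [c for c in names if c not in self.table.columns]
        if missing:
            raise KeyError(f"covariate columns not in cohort table: {missing}")
        mat = self.table[names].to_numpy(dtype=float)
        if not np.isfinite(mat).all():
            raise ValueError("covariate columns contain missing/non-finite values")
        return mat


def read_cohort(path: str | Path, group_order: list[str] | None = None) -> CohortTable:
    """Read a delimited cohort table.

    Parameters
    ----------
    path : path
        CSV with a header containing at least ``subject_id`` and ``group``.
    group_order : list of str, optional
        Explicit level ordering; defaults to file order of first appearance.

    Raises
    ------
    ValueError
        On duplicate subject ids, missing mandatory columns, or fewer than
        two non-empty group levels.
    """
    df = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"cohort table must contain a {col!r} column")
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dup = df["subject_id"][df["subject_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate subject_id {dup!r}")
    df = df.set_index("subject_id")
    df["group"] = df["group"].astype(str)
    levels = group_order if group_order is not None else list(dict.fromkeys(df["group"]))
    unknown = set(df["group"]) - set(levels)
    if unknown:
        raise ValueError(f"group labels not in requested order: {sorted(unknown)}")
    present = [g for g in levels if (df["group"] == g).any()]
    if len(present) < 2:
        raise ValueError("cohort must contain at least two non-empty group levels")
    for col in df.columns:
        if col == "group":
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric value in covariate column {col!r}") from exc
    return CohortTable(table=df, group_levels=list(levels))


@dataclass
class FCBundle:
    """Per-subject per-band symmetric connectivity matrices.

    ``matrices[(subject, band)]`` is an (R, R) float array in canonical
    atlas region order, symmetric with zero diagonal and entries in [0, 1].
    """

    subjects: list[str]
    bands: list[str]
    matrices: dict[tuple[str, str], np.ndarray]
    manifest: dict = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        first = self.matrices[(self.subjects[0], self.bands[0])]
        return first.shape[0]

    def validate(self) -> None:
        if len(set(self.subjects)) != len(self.subjects):
            raise BundleIntegrityError("duplicate subject ids in bundle")
        for s in self.subjects:
            for b in self.bands:
                if (s, b) not in self.matrices:
                    raise BundleIntegrityError(f"missing matrix for ({s!r}, {b!r})")
                m = self.matrices[(s, b)]
                if m.ndim != 2 or m.shape[0] != m.shape[1]:
                    raise BundleIntegrityError(f"matrix for ({s!r}, {b!r}) not square")

    def edge_matrix(self, band: str) -> np.ndarray:
        """Stack upper-triangle edge values into an (N_subjects, E) matrix.

        Edge order follows ``numpy.triu_indices(R, 1)`` and is shared by the
        statistics modules.
        """
        r = self.n_regions
        iu = np.triu_indices(r, 1)
        return np.stack([self.matrices[(s, band)][iu] for s in self.subjects])


def write_fc_bundle(bundle: FCBundle, directory: str | Path) -> Path:
    """Write a bundle as delimited matrices plus ``manifest.json``.

    Returns the manifest path.  Matrices are stored full (symmetric) with
    17 significant digits, so reading them back reproduces every entry
    bit-exactly.
    """
    bundle.validate()
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files = {}
    for s in bundle.subjects:
        for b in bundle.bands:
            fname = f"{s}__{b}.tsv"
            np.savetxt(d / fname, bundle.matrices[(s, b)], fmt="%.17g", delimiter="\t")
            files[f"{s}\t{b}"] = fname
    manifest = {
        "subjects": bundle.subjects,
        "bands": bundle.bands,
        "files": files,
        "provenance": bundle.manifest,
    }
    mpath = d / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_fc_bundle(directory: str | Path) -> FCBundle:
    """Read a bundle written by :func:`write_fc_bundle`."""
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    matrices = {}
    for key, fname in manifest["files"].items():
        subject, band = key.split("\t")
        fpath = d / fname
        if not fpath.exists():
            raise BundleIntegrityError(f"manifest references absent file {fname!r}")
        matrices[(subject, band)] = np.loadtxt(fpath, delimiter="\t", ndmin=2)
    bundle = FCBundle(
        subjects=list(manifest["subjects"]),
        bands=list(manifest["bands"]),
        matrices=matrices,
        manifest=manifest.get("provenance", {}),
    )
    bundle.validate()
    return bundle
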