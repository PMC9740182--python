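"""Cohort file I/O and element-to-sulfur ratio preprocessing.

On-disk layout of a cohort bundle::

    <dir>/manifest.json          schema "hairdyn-manifest-v1": config echo,
                                 seed, file list
    <dir>/metadata.csv           subject_id, diagnosis, sex, age_months,
                                 site, batch
    <dir>/strands/<sid>.csv      columns: point, <element labels...>, S

Preprocessing follows the density-normalization rationale of single-strand
laser-ablation ICP-MS: every element trace is divided point-wise by the
sulfur trace, which cancels variation in ablated hair mass.  Points where
sulfur is non-positive or any channel is non-finite are dropped from *all*
elements of that subject (a common retained index), because the downstream
recurrence analysis needs an evenly indexed series shared across channels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CohortConfig, StrandProfile, SubjectRecord

__all__ = [
    "MANIFEST_SCHEMA",
    "RatioSeries",
    "write_cohort",
    "read_cohort",
    "retained_index",
    "to_ratio_series",
    "ratio_frame",
]

MANIFEST_SCHEMA = "hairdyn-manifest-v1"
logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RatioSeries:
    """One element's sulfur-normalized series: the unit of dynamical analysis."""

    subject_id: str
    element: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite ratio values for {self.subject_id}/{self.element}")
        object.__setattr__(self, "values", values)

    @property
    def n_points(self) -> int:
        return len(self.values)


def write_cohort(records: list[SubjectRecord], profiles: list[StrandProfile],
                 out_dir: str | Path, config: CohortConfig | None = None) -> Path:
    """Write a cohort bundle; returns the manifest path."""
    out = Path(out_dir)
    (out / "strands").mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "diagnosis": [r.diagnosis for r in records],
            "sex": [r.sex for r in records],
            "age_months": [r.age_months for r in records],
            "site": [r.site for r in records],
            "batch": [r.batch for r in records],
        }
    )
    meta.to_csv(out / "metadata.csv", index=False, float_format="%.17g")

    panel = profiles[0].elements if profiles else ()
    files = {}
    for profile in profiles:
        df = pd.DataFrame({"point": np.arange(profile.n_points)})
        for el in profile.elements:
            df[el] = profile.channels[el]
        df["S"] = profile.sulfur
        rel = f"strands/{profile.subject_id}.csv"
        df.to_csv(out / rel, index=False, float_format="%.17g")
        files[profile.subject_id] = rel

    manifest = {
        "schema": MANIFEST_SCHEMA,
        "panel": list(panel),
        "config": None if config is None else {
            **{k: (sorted(v) if isinstance(v, frozenset) else v)
               for k, v in config.__dict__.items()},
        },
        "seed": None if config is None else config.seed,
        "metadata": "metadata.csv",
        "strands": files,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort(manifest_path: str | Path) -> tuple[list[SubjectRecord], list[StrandProfile]]:
    """Read a cohort bundle written by :func:`write_cohort`.

    Raises if a strand file is missing (naming the subject), if a strand's
    columns do not match the declared panel, on duplicate subject ids, or on
    negative intensities.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("schema") != MANIFEST_SCHEMA:
        raise ValueError(f"unsupported manifest schema: {manifest.get('schema')!r}")
    panel = list(manifest["panel"])

    meta = pd.read_csv(root / manifest["metadata"], float_precision="round_trip")
    if meta["subject_id"].duplicated().any():
        dupes = meta.loc[meta["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id in metadata: {dupes}")
    records = [
        SubjectRecord(
            subject_id=str(row.subject_id),
            diagnosis=str(row.diagnosis),
            sex=str(row.sex),
            age_months=float(row.age_months),
            site=str(row.site),
            batch=str(row.batch),
        )
        for row in meta.itertuples()
    ]

    profiles: list[StrandProfile] = []
    for sid, rel in manifest["strands"].items():
        path = root / rel
        if not path.exists():
            raise FileNotFoundError(f"strand file missing for subject {sid}: {path}")
        df = pd.read_csv(path, float_precision="round_trip")
        expected = ["point", *panel, "S"]
        if list(df.columns) != expected:
            raise ValueError(
                f"strand columns for subject {sid} do not match the declared panel: "
                f"got {list(df.columns)}, expected {expected}"
            )
        channels = {el: df[el].to_numpy(dtype=float) for el in panel}
        profiles.append(StrandProfile(subject_id=sid, channels=channels,
                                      sulfur=df["S"].to_numpy(dtype=float)))
    return records, profiles


def retained_index(profile: StrandProfile) -> np.ndarray:
    """Common retained-point index for a subject.

    A point survives iff sulfur > 0 there and every element channel is
    finite; listwise deletion keeps all channels on one shared index.
    """
    keep = np.isfinite(profile.sulfur) & (profile.sulfur > 0)
    for series in profile.channels.values():
        keep &= np.isfinite(series)
    return np.flatnonzero(keep)


def to_ratio_series(profile: StrandProfile, element: str,
                    max_drop_fraction: float = 0.10) -> RatioSeries:
    """Element-to-sulfur ratio series over the subject's common retained index.

    Errors if the element is absent or if more than ``max_drop_fraction`` of
    points would be dropped (an unusable strand).
    """
    if element not in profile.channels:
        raise KeyError(f"element {element!r} not measured for subject {profile.subject_id}; "
                       f"panel is {profile.elements}")
    keep = retained_index(profile)
    dropped = profile.n_points - len(keep)
    if dropped:
        logger.info("subject %s: dropped %d/%d points (non-positive sulfur or "
                    "non-finite channel)", profile.subject_id, dropped, profile.n_points)
    if dropped > max_drop_fraction * profile.n_points:
        raise ValueError(
            f"subject {profile.subject_id}: {dropped}/{profile.n_points} points dropped "
            f"(> {max_drop_fraction:.0%}); strand unusable"
        )
    values = profile.channels[element][keep] / profile.sulfur[keep]
    return RatioSeries(subject_id=profile.subject_id, element=element, values=values)


def ratio_frame(profile: StrandProfile, panel: list[str] | None = None,
                max_drop_fraction: float = 0.10) -> pd.DataFrame:
    """All ratio series of one subject as a DataFrame (columns = elements)."""
    panel = list(profile.elements) if panel is None else list(panel)
    return pd.DataFrame(
        {el: to_ratio_series(profile, el, max_drop_fraction).values for el in panel}
    )
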