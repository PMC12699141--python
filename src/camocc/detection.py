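"""Detection-history construction from camera-trap photo records.

A camera-trap survey yields timestamped photo records per station and a
deployment table giving each station's active period.  For occupancy
analysis these are collapsed into a sites x occasions binary matrix, where
an occasion is a fixed-length block of trap-days (4 days by default) and a
cell is 1 if at least one target-species photo fell inside that block, 0 if
the camera was active but recorded none, and missing if the camera was
inactive for the entire block.

Occasions are anchored per site at its deployment start; stations surveyed
in different years therefore do not need to share calendar windows.  A
final short occasion (deployment length not divisible by the occasion
length) is retained and flagged rather than dropped, and an occasion during
which the camera was active for at least one day counts as surveyed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DetectionMatrix",
    "build_matrix",
    "independent_detections",
    "naive_occupancy",
    "naive_detection_rate",
    "read_photos",
    "read_deployments",
]


@dataclass
class DetectionMatrix:
    """Sites x occasions binary detection records.

    Parameters
    ----------
    data : ndarray of shape (n_sites, n_occasions)
        Float array with cells in {0.0, 1.0, nan}; nan marks occasions in
        which the camera was inactive for the whole window.
    site_ids : list
        Ordered site identifiers, one per row.
    occasion_length : int
        Occasion window length in days.
    anchors : dict, optional
        site_id -> ISO date string of the occasion grid origin
        (deployment start).
    short_final : list
        Site ids whose final occasion is shorter than ``occasion_length``.
    """

    data: np.ndarray
    site_ids: list
    occasion_length: int = 4
    anchors: dict | None = None
    short_final: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-dimensional (sites x occasions)")
        if len(self.site_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.site_ids)} site ids for {self.data.shape[0]} rows"
            )
        finite = self.data[~np.isnan(self.data)]
        if not np.all((finite == 0.0) | (finite == 1.0)):
            raise ValueError("cells must be 0, 1 or missing (nan)")
        if self.data.shape[0] and np.any(np.all(np.isnan(self.data), axis=1)):
            raise ValueError("every site must have at least one surveyed occasion")

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.data.shape[1]

    def observed(self) -> np.ndarray:
        """Boolean mask of surveyed (non-missing) cells."""
        return ~np.isnan(self.data)

    def detected_sites(self) -> np.ndarray:
        """Boolean vector: site had at least one detection."""
        return np.any(self.data == 1.0, axis=1)

    def subset(self, index) -> "DetectionMatrix":
        """Row subset preserving metadata (used for cross-validation folds)."""
        index = np.asarray(index)
        ids = [self.site_ids[i] for i in index]
        anchors = (
            {s: self.anchors[s] for s in ids if s in self.anchors}
            if self.anchors
            else None
        )
        return DetectionMatrix(
            self.data[index],
            ids,
            self.occasion_length,
            anchors,
            [s for s in self.short_final if s in set(ids)],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"occ_{j + 1}" for j in range(self.n_occasions)]
        frame = pd.DataFrame(self.data, columns=cols)
        frame.insert(0, "site_id", self.site_ids)
        return frame

    def to_csv(self, path) -> None:
        """Write the matrix as CSV (cells 0/1/NA) plus a JSON metadata sidecar."""
        path = Path(path)
        frame = self.to_frame()
        out = frame.copy()
        for c in out.columns[1:]:
            out[c] = out[c].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
        out.to_csv(path, index=False)
        meta = {
            "occasion_length": self.occasion_length,
            "anchors": self.anchors,
            "short_final": self.short_final,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, sort_keys=True, indent=2)
        )

    @classmethod
    def from_csv(cls, path) -> "DetectionMatrix":
        path = Path(path)
        frame = pd.read_csv(path, na_values=["NA"])
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            frame.iloc[:, 1:].to_numpy(dtype=float),
            frame.iloc[:, 0].tolist(),
            int(meta.get("occasion_length", 4)),
            meta.get("anchors"),
            meta.get("short_final", []),
        )


def read_photos(path, target_species: str | None = None) -> pd.DataFrame:
    """Read a photo-record CSV (columns site_id, timestamp, species).

    ``is_target`` is derived from the species column when ``target_species``
    is given; otherwise every record is treated as a target photo.
    """
    photos = pd.read_csv(path)
    photos["timestamp"] = pd.to_datetime(photos["timestamp"])
    if "is_target" in photos.columns:
        photos["is_target"] = photos["is_target"].astype(bool)
    elif target_species is not None and "species" in photos.columns:
        photos["is_target"] = photos["species"] == target_species
    else:
        photos["is_target"] = True
    return photos


def read_deployments(path) -> pd.DataFrame:
    """Read a deployment CSV (columns site_id, start, end; inclusive dates)."""
    dep = pd.read_csv(path)
    dep["start"] = pd.to_datetime(dep["start"])
    dep["end"] = pd.to_datetime(dep["end"])
    if (dep["end"] < dep["start"]).any():
        bad = dep.loc[dep["end"] < dep["start"], "site_id"].tolist()
        raise ValueError(f"deployment end before start for sites {bad}")
    return dep


def build_matrix(
    photos: pd.DataFrame,
    deployments: pd.DataFrame,
    occasion_length: int = 4,
    on_outside: str = "warn",
) -> DetectionMatrix:
    """Collapse photo records into a binary detection matrix.

    Parameters
    ----------
    photos : DataFrame
        Columns ``site_id``, ``timestamp`` and optionally ``is_target``
        (all records are target photos when absent).
    deployments : DataFrame
        Columns ``site_id``, ``start``, ``end`` — inclusive active dates.
        Multiple rows per site describe interrupted deployments; occasions
        wholly inside a gap become missing cells.
    occasion_length : int
        Days per survey occasion (>= 1).
    on_outside : {"warn", "error"}
        Policy for target photos falling outside every deployment window
        of their site: drop with a warning, or raise.

    Returns
    -------
    DetectionMatrix
        One row per site (deployment-table order), padded with missing
        cells to the longest site's occasion count.
    """
    if occasion_length < 1:
        raise ValueError("occasion_length must be >= 1 day")
    if on_outside not in ("warn", "error"):
        raise ValueError("on_outside must be 'warn' or 'error'")
    deployments = deployments.copy()
    deployments["start"] = pd.to_datetime(deployments["start"]).dt.normalize()
    deployments["end"] = pd.to_datetime(deployments["end"]).dt.normalize()
    if (deployments["end"] < deployments["start"]).any():
        raise ValueError("deployment end precedes start")

    site_ids = list(dict.fromkeys(deployments["site_id"]))
    known = set(site_ids)
    photos = photos.copy()
    if "is_target" not in photos.columns:
        photos["is_target"] = True
    photos["timestamp"] = pd.to_datetime(photos["timestamp"])
    unknown = set(photos["site_id"]) - known
    if unknown:
        raise ValueError(f"photo records reference unknown sites: {sorted(unknown)}")

    by_site = {s: g for s, g in deployments.groupby("site_id", sort=False)}
    target = photos[photos["is_target"]]
    photos_by_site = {s: g for s, g in target.groupby("site_id", sort=False)}

    day = pd.Timedelta(days=1)
    rows, anchors, short_final = [], {}, []
    n_occ = []
    for site in site_ids:
        dep = by_site[site]
        anchor = dep["start"].min()
        end_excl = dep["end"].max() + day
        total_days = (end_excl - anchor).days
        j_site = math.ceil(total_days / occasion_length)
        n_occ.append(j_site)
        anchors[site] = anchor.date().isoformat()
        if total_days % occasion_length:
            short_final.append(site)

        # surveyed iff the camera was active >= 1 day of the window
        row = np.full(j_site, np.nan)
        intervals = [(s, e + day) for s, e in zip(dep["start"], dep["end"])]
        for j in range(j_site):
            w0 = anchor + j * occasion_length * day
            w1 = min(anchor + (j + 1) * occasion_length * day, end_excl)
            active = sum(
                max(0.0, (min(w1, e) - max(w0, s)) / day) for s, e in intervals
            )
            if active > 0:
                row[j] = 0.0

        for t in photos_by_site.get(site, pd.DataFrame(columns=["timestamp"]))[
            "timestamp"
        ]:
            if not any(s <= t < e for s, e in intervals):
                msg = f"photo at {t} outside all deployments of site {site!r}"
                if on_outside == "error":
                    raise ValueError(msg)
                warnings.warn(msg + "; record dropped", stacklevel=2)
                continue
            j = (t.normalize() - anchor).days // occasion_length
            row[j] = 1.0
        rows.append(row)

    width = max(n_occ)
    data = np.full((len(site_ids), width), np.nan)
    for i, row in enumerate(rows):
        data[i, : len(row)] = row
    return DetectionMatrix(data, site_ids, occasion_length, anchors, short_final)


def independent_detections(photos: pd.DataFrame, window: float = 60.0) -> int:
    """Count independent detection events.

    Consecutive target photos at the same site closer than ``window``
    minutes collapse into a single event (chain rule: a new event starts
    when the gap from the previous photo reaches the window).
    """
    if window <= 0:
        raise ValueError("window must be positive (minutes)")
    if len(photos) == 0:
        return 0
    photos = photos.copy()
    if "is_target" not in photos.columns:
        photos["is_target"] = True
    photos["timestamp"] = pd.to_datetime(photos["timestamp"])
    target = photos[photos["is_target"]]
    if len(target) == 0:
        return 0
    gap = pd.Timedelta(minutes=window)
    events = 0
    for _, g in target.groupby("site_id", sort=False):
        ts = g["timestamp"].sort_values().to_numpy()
        events += 1 + int(np.sum(np.diff(ts) >= gap))
    return events


def naive_occupancy(matrix: DetectionMatrix) -> float:
    """Fraction of sites with at least one detection (no detection correction)."""
    if matrix.n_sites == 0:
        raise ValueError("naive occupancy undefined for zero sites")
    return float(matrix.detected_sites().mean())


def naive_detection_rate(matrix: DetectionMatrix) -> float:
    """Detections per surveyed occasion among sites with >= 1 detection.

    The customary summary of raw detectability: occasions at never-detected
    sites are excluded because their occupancy state is unknown.
    """
    det = matrix.detected_sites()
    if not det.any():
        return 0.0
    sub = matrix.data[det]
    return float(np.nansum(sub) / np.sum(~np.isnan(sub)))
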