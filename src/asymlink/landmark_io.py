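"""Reading and writing landmark data in the TPS dialect.

TPS files (as produced by tpsUtil/tpsDig) are plain text: each record
starts with ``LM=<k>`` followed by ``k`` lines of ``x y`` coordinates
and optional ``IMAGE=``, ``ID=`` and ``SCALE=`` lines.  Keys are
case-insensitive; unknown keys are carried through as opaque metadata.
Coordinates are Cartesian with y increasing upward (the tpsDig
convention) -- no axis flip is applied on read, so reflection
operations downstream are unambiguous.

Classifier metadata (individual, side, replicate numbers, nest,
location, species) lives in a separate CSV keyed by record ID (or image
basename when no ID is present) and is joined onto the records at read
time.  Landmark indices are 1-based in all user-facing I/O, matching
TPS numbering.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "LandmarkDataset",
    "TPSParseError",
    "DatasetError",
    "PairingError",
    "read_tps",
    "write_tps",
    "validate_pairing",
]

_SIDES = {"left", "right", "none"}

#: classifier labels recognised in classifier tables
CLASSIFIER_FIELDS = ("individual", "side", "image_rep", "digit_rep", "nest", "location", "species")


class TPSParseError(ValueError):
    """Malformed TPS record."""


class DatasetError(ValueError):
    """Inconsistent landmark dataset (e.g. mixed landmark counts)."""


class PairingError(ValueError):
    """Invalid object-symmetry pairing map."""


@dataclass
class LandmarkConfiguration:
    """One digitized landmark configuration with its classifiers."""

    specimen_id: str
    coords: np.ndarray  # (k, 2), scale already applied
    scale: float | None = None
    classifiers: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)  # unknown TPS keys, carried through

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"{self.specimen_id}: coords must be (k, 2)")
        if self.k < 3:
            raise ValueError(f"{self.specimen_id}: need at least 3 landmarks, got {self.k}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinates")
        side = self.classifiers.get("side", "none")
        if side not in _SIDES:
            raise ValueError(f"{self.specimen_id}: side must be one of {_SIDES}, got {side!r}")
        self.classifiers.setdefault("side", "none")
        self.classifiers.setdefault("individual", self.specimen_id)
        for rep in ("image_rep", "digit_rep"):
            self.classifiers[rep] = int(self.classifiers.get(rep, 1) or 1)
            if self.classifiers[rep] < 1:
                raise ValueError(f"{self.specimen_id}: {rep} must be >= 1")

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass
class LandmarkDataset:
    """A set of configurations of one bilateral structure.

    ``symmetry_mode`` is ``"matching"`` for paired structures (left and
    right wings are separate configurations) and ``"object"`` for
    structures with an internal midline (heads), in which case
    ``pairing`` lists the 1-based (left, right) landmark index pairs and
    ``midline`` the on-axis landmark indices.
    """

    configs: list
    symmetry_mode: str = "matching"
    pairing: list = field(default_factory=list)  # [(left_idx, right_idx)], 1-based
    midline: list = field(default_factory=list)

    def __post_init__(self):
        if self.symmetry_mode not in ("matching", "object"):
            raise ValueError(f"symmetry_mode must be 'matching' or 'object', got {self.symmetry_mode!r}")
        ks = {c.k for c in self.configs}
        if len(ks) > 1:
            raise DatasetError(
                f"configurations disagree on landmark count {sorted(ks)}; "
                "structures with different landmark schemes are separate datasets"
            )
        # the pairing may be attached after reading; it is validated
        # here when present and (again) at decomposition time
        if self.symmetry_mode == "object" and self.configs and (self.pairing or self.midline):
            validate_pairing(self.pairing, self.midline, self.k)

    @property
    def k(self) -> int:
        if not self.configs:
            return 0
        return self.configs[0].k

    def __len__(self) -> int:
        return len(self.configs)

    def coords_array(self) -> np.ndarray:
        return np.stack([c.coords for c in self.configs]) if self.configs else np.empty((0, 0, 2))

    def classifier_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.configs:
            row = {"specimen_id": c.specimen_id}
            row.update({f: c.classifiers.get(f) for f in CLASSIFIER_FIELDS})
            rows.append(row)
        return pd.DataFrame(rows)


def validate_pairing(pairing, midline, k: int):
    """Check that pairs and midline partition the 1..k landmark indices.

    ``pairing`` may list each pair once in either orientation; it must
    be an involution (no index on both sides of different pairs).
    Returns the pairing as a list of (left, right) tuples.
    """
    pairing = [tuple(int(i) for i in p) for p in pairing]
    midline = [int(i) for i in midline]
    seen: dict[int, int] = {}
    problems = []
    for a, b in pairing:
        if a == b:
            problems.append(f"pair ({a},{b}) maps an index to itself")
        for idx in (a, b):
            if not (1 <= idx <= k):
                problems.append(f"index {idx} outside 1..{k}")
    flat = [i for p in pairing for i in p] + list(midline)
    counts = pd.Series(flat).value_counts() if flat else pd.Series(dtype=int)
    dup = sorted(counts[counts > 1].index.tolist())
    missing = sorted(set(range(1, k + 1)) - set(flat))
    if dup:
        problems.append(f"duplicated indices: {dup}")
    if missing:
        problems.append(f"unassigned indices: {missing}")
    if problems:
        raise PairingError("; ".join(problems))
    del seen
    return pairing


def _parse_kv(line: str):
    if "=" not in line:
        return None
    key, _, value = line.partition("=")
    key = key.strip()
    if not key or " " in key:
        return None
    return key.upper(), value.strip()


def read_tps(path, classifier_table=None) -> LandmarkDataset:
    """Read a TPS file, joining an optional classifier CSV.

    The classifier table (path or DataFrame) must have an ``id`` column
    whose values match record IDs (preferred) or image basenames; its
    remaining recognised columns populate each configuration's
    classifiers.  Classifier keys that match no record raise an error
    listing them. Record order is preserved; parsing is insensitive to
    line-ending dialect and trailing blank lines.
    """
    with open(path, "r", newline="") as fh:
        lines = [ln.strip() for ln in fh.read().splitlines()]

    records = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i]
        if not line:
            i += 1
            continue
        kv = _parse_kv(line)
        if kv is None or kv[0] != "LM":
            raise TPSParseError(f"{path}: expected 'LM=' at line {i + 1}, got {line!r}")
        try:
            k = int(kv[1])
        except ValueError:
            raise TPSParseError(f"{path}: bad landmark count {kv[1]!r} at line {i + 1}") from None
        i += 1
        coords = []
        while i < n_lines and len(coords) < k:
            if not lines[i]:
                i += 1
                continue
            parts = lines[i].split()
            if len(parts) != 2:
                break
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError:
                break
            i += 1
        record_no = len(records) + 1
        if len(coords) != k:
            raise TPSParseError(
                f"{path}: record {record_no} declares LM={k} but has {len(coords)} coordinate lines"
            )
        meta = {}
        while i < n_lines:
            if not lines[i]:
                i += 1
                continue
            kv = _parse_kv(lines[i])
            if kv is None or kv[0] == "LM":
                break
            meta[kv[0]] = kv[1]
            i += 1
        records.append((record_no, k, np.array(coords, dtype=float), meta))

    table = None
    if classifier_table is not None:
        table = (
            pd.read_csv(classifier_table, dtype=str)
            if not isinstance(classifier_table, pd.DataFrame)
            else classifier_table.astype(str)
        )
        if "id" not in table.columns:
            raise DatasetError("classifier table must have an 'id' column")
        table = table.set_index("id")

    configs = []
    matched_keys = set()
    for record_no, k, coords, meta in records:
        scale = None
        if "SCALE" in meta:
            scale = float(meta.pop("SCALE"))
            coords = coords * scale
        image = meta.pop("IMAGE", None)
        rec_id = meta.pop("ID", None)
        if rec_id is not None:
            key = rec_id
        elif image is not None:
            key = os.path.splitext(os.path.basename(image))[0]
        else:
            key = f"record{record_no}"
        classifiers = {}
        if table is not None and key in table.index:
            matched_keys.add(key)
            row = table.loc[key]
            for f in CLASSIFIER_FIELDS:
                if f in table.columns and pd.notna(row[f]) and row[f] != "nan":
                    classifiers[f] = row[f]
        extra = dict(meta)
        if image is not None:
            extra["IMAGE"] = image
        configs.append(
            LandmarkConfiguration(
                specimen_id=key, coords=coords, scale=scale, classifiers=classifiers, extra=extra
            )
        )

    if table is not None:
        unmatched = sorted(set(table.index) - matched_keys)
        if unmatched:
            raise DatasetError(f"classifier keys match no TPS record: {unmatched}")

    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise DatasetError(
            f"{path}: mixed landmark counts {sorted(ks)}; split structures into separate files"
        )
    side_vals = {c.classifiers.get("side", "none") for c in configs}
    mode = "object" if side_vals <= {"none"} else "matching"
    return LandmarkDataset(configs=configs, symmetry_mode=mode)


def write_tps(dataset: LandmarkDataset, path, classifier_path=None):
    """Write a dataset to TPS text (plus a classifier CSV).

    Coordinates are written with 17 significant digits so that
    ``read_tps(write_tps(d))`` reproduces them to full float precision.
    Classifiers round-trip through the sidecar CSV (default
    ``<path>.classifiers.csv``); pass ``classifier_path=False`` to skip
    it.
    """
    with open(path, "w") as fh:
        for c in dataset.configs:
            fh.write(f"LM={c.k}\n")
            for x, y in c.coords:
                fh.write(f"{x:.17g} {y:.17g}\n")
            fh.write(f"ID={c.specimen_id}\n")
            for key, value in c.extra.items():
                fh.write(f"{key}={value}\n")
    if classifier_path is False:
        return
    if classifier_path is None:
        classifier_path = f"{path}.classifiers.csv"
    frame = dataset.classifier_frame().rename(columns={"specimen_id": "id"})
    if len(frame):
        frame.dropna(axis=1, how="all").to_csv(classifier_path, index=False)


def read_pairing_yaml(path):
    """Load a pairing map from YAML: ``pairs: [[l, r], ...]`` and ``midline: [...]``."""
    import yaml

    with open(path) as fh:
        spec = yaml.safe_load(fh)
    pairs = [tuple(p) for p in spec.get("pairs", [])]
    midline = list(spec.get("midline", []))
    return pairs, midline


def warn_excluded(ids, reason):
    if ids:
        warnings.warn(f"excluded {len(ids)} individual(s) ({reason}): {sorted(ids)}", stacklevel=3)
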