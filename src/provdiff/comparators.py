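"""File-equality comparators and segmentation similarity metrics.

Whether two conditions "agree" on a file is not always a byte question:
many scientific formats embed timestamps, hostnames or header fields
that legitimately differ between runs.  The labeling engine therefore
decides equality through a :class:`ComparatorRegistry` — an ordered
list of (path glob → comparator) rules with a checksum default — so
type-aware rules can ignore headers or timestamp lines.

The module also provides the segmentation comparison metrics used to
quantify how differences manifest in imaging outputs: the Dice overlap
coefficient, its per-region table, and voxel-wise binarized difference
counts across subject pairs.
"""

from __future__ import annotations

import fnmatch
import hashlib
import os
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ComparatorRegistry",
    "ComparatorRule",
    "SegmentationMask",
    "ComparatorConfigError",
    "UndefinedDiceError",
    "checksum_equal",
    "compare_files",
    "dice_coefficient",
    "per_region_dice",
    "binarized_difference_sum",
]


class ComparatorConfigError(ValueError):
    """The registry references an unknown comparator id."""


class UndefinedDiceError(ZeroDivisionError):
    """Dice is undefined when both voxel sets are empty."""


def _digest(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def checksum_equal(a: str | os.PathLike, b: str | os.PathLike) -> bool:
    """True iff the SHA-256 digests of the two files' contents agree."""
    return _digest(a) == _digest(b)


# ---------------------------------------------------------------------------
# Built-in comparators.  Each takes (a, b, params) and returns
# (equal: bool, detail: str).

def _cmp_checksum(a, b, params):
    equal = checksum_equal(a, b)
    return equal, "sha256 equal" if equal else "sha256 differ"


def _cmp_skip_bytes(a, b, params):
    """Byte equality outside the configured [start, end) windows.

    ``params["ranges"]`` is a list of [start, end) byte windows to
    ignore — e.g. a fixed-size binary header.
    """
    ranges = [(int(s), int(e)) for s, e in params.get("ranges", [])]
    da, db = Path(a).read_bytes(), Path(b).read_bytes()
    if len(da) != len(db):
        return False, f"size differs: {len(da)} vs {len(db)}"
    mask = np.ones(len(da), dtype=bool)
    for s, e in ranges:
        mask[s:e] = False
    xa = np.frombuffer(da, dtype=np.uint8)
    xb = np.frombuffer(db, dtype=np.uint8)
    equal = bool(np.array_equal(xa[mask], xb[mask]))
    return equal, "equal outside ignored ranges" if equal else "payload differs"


_DEFAULT_TIMESTAMP_PATTERNS = (
    r"\d{4}-\d{2}-\d{2}[ T]\d{2}:\d{2}(:\d{2})?",
    r"\d{2}:\d{2}:\d{2}",
    r"(?i)^(date|time|timestamp)\b.*",
)


def _cmp_text_no_timestamps(a, b, params):
    """Line-wise text equality, dropping lines that match timestamp patterns."""
    patterns = [re.compile(p) for p in params.get(
        "patterns", _DEFAULT_TIMESTAMP_PATTERNS)]

    def keep(lines):
        return [ln for ln in lines if not any(p.search(ln) for p in patterns)]

    la = keep(Path(a).read_text(errors="replace").splitlines())
    lb = keep(Path(b).read_text(errors="replace").splitlines())
    equal = la == lb
    return equal, "text equal ignoring timestamps" if equal else "text differs"


def _cmp_nifti_data(a, b, params):
    """Voxel-data equality of two NIfTI volumes, ignoring the header."""
    import nibabel as nib

    ia, ib = nib.load(str(a)), nib.load(str(b))
    da = np.asanyarray(ia.dataobj)
    db = np.asanyarray(ib.dataobj)
    if da.shape != db.shape:
        return False, f"shape differs: {da.shape} vs {db.shape}"
    equal = bool(np.array_equal(da, db))
    return equal, "voxel data equal" if equal else "voxel data differ"


BUILTIN_COMPARATORS = {
    "checksum": _cmp_checksum,
    "skip-bytes": _cmp_skip_bytes,
    "text-no-timestamps": _cmp_text_no_timestamps,
    "nifti-data": _cmp_nifti_data,
}


@dataclass(frozen=True)
class ComparatorRule:
    pattern: str
    comparator: str
    params: dict = field(default_factory=dict)


@dataclass
class ComparatorRegistry:
    """Ordered dispatch of path patterns to comparators; first match wins.

    The default comparator (exact SHA-256 checksum) applies when no rule
    matches, so an empty registry is byte-exact comparison.
    """

    rules: list[ComparatorRule] = field(default_factory=list)
    default: str = "checksum"

    def __post_init__(self) -> None:
        self._check(self.default)
        for rule in self.rules:
            self._check(rule.comparator)

    @staticmethod
    def _check(comparator_id: str) -> None:
        if comparator_id not in BUILTIN_COMPARATORS:
            raise ComparatorConfigError(
                f"unknown comparator id {comparator_id!r}; "
                f"known: {sorted(BUILTIN_COMPARATORS)}"
            )

    def add_rule(self, pattern: str, comparator: str, **params) -> None:
        self._check(comparator)
        self.rules.append(ComparatorRule(pattern, comparator, params))

    def _select(self, key_path: str) -> tuple[str, dict]:
        name = os.path.basename(key_path)
        for rule in self.rules:
            if fnmatch.fnmatchcase(key_path, rule.pattern) or fnmatch.fnmatchcase(
                name, rule.pattern
            ):
                return rule.comparator, rule.params
        return self.default, {}

    def compare(
        self, key_path: str, a: str | os.PathLike, b: str | os.PathLike
    ) -> tuple[bool, str]:
        """Compare files ``a`` and ``b`` under the rule selected by ``key_path``."""
        comparator, params = self._select(key_path)
        equal, detail = BUILTIN_COMPARATORS[comparator](a, b, params)
        return equal, f"{comparator}: {detail}"

    @classmethod
    def from_config(cls, config: dict) -> "ComparatorRegistry":
        """Build from ``{"default": id, "rules": [{"pattern", "comparator",
        "params"?}, ...]}``."""
        rules = [
            ComparatorRule(
                r["pattern"], r["comparator"], dict(r.get("params", {}))
            )
            for r in config.get("rules", [])
        ]
        return cls(rules=rules, default=config.get("default", "checksum"))


def compare_files(
    a: str | os.PathLike, b: str | os.PathLike, registry: ComparatorRegistry,
    key_path: str | None = None,
) -> tuple[bool, str]:
    """Verdict for two files under the registry (dispatch by ``key_path``,
    defaulting to ``a``'s own path)."""
    return registry.compare(str(key_path if key_path is not None else a), a, b)


# ---------------------------------------------------------------------------
# Segmentation metrics

@dataclass
class SegmentationMask:
    """Integer-labeled voxel grid (0 = background)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("segmentation labels must be integral")
            self.data = np.round(self.data).astype(np.int64)
        if (self.data < 0).any():
            raise ValueError("segmentation labels must be non-negative")

    @classmethod
    def from_nifti(cls, path: str | os.PathLike) -> "SegmentationMask":
        import nibabel as nib

        return cls(np.asanyarray(nib.load(str(path)).dataobj))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxel_set(self, label: int | None = None) -> np.ndarray:
        """Boolean grid: voxels carrying ``label`` (or any nonzero label)."""
        if label is None:
            return self.data != 0
        return self.data == label

    def region_labels(self) -> np.ndarray:
        labels = np.unique(self.data)
        return labels[labels != 0]


def _as_mask(x) -> SegmentationMask:
    return x if isinstance(x, SegmentationMask) else SegmentationMask(x)


def dice_coefficient(x, y, label: int | None = None) -> float:
    """Dice overlap 2|X∩Y| / (|X|+|Y|) between two segmentations.

    ``X`` and ``Y`` are the voxel sets carrying ``label`` (all nonzero
    labels when ``label`` is None).  1 is perfect overlap, 0 disjoint.
    Raises on shape mismatch and when both sets are empty (undefined).
    """
    mx, my = _as_mask(x), _as_mask(y)
    if mx.shape != my.shape:
        raise ValueError(f"grid shapes differ: {mx.shape} vs {my.shape}")
    sx, sy = mx.voxel_set(label), my.voxel_set(label)
    denom = int(sx.sum()) + int(sy.sum())
    if denom == 0:
        raise UndefinedDiceError("Dice undefined: both voxel sets are empty")
    return 2.0 * int((sx & sy).sum()) / denom


def per_region_dice(x, y) -> pd.Series:
    """One Dice value per region label present in either mask.

    A label present in only one mask scores 0.  Returned as a Series
    indexed by region label, sorted by label.
    """
    mx, my = _as_mask(x), _as_mask(y)
    if mx.shape != my.shape:
        raise ValueError(f"grid shapes differ: {mx.shape} vs {my.shape}")
    labels = np.union1d(mx.region_labels(), my.region_labels())
    values = [dice_coefficient(mx, my, label=int(lbl)) for lbl in labels]
    return pd.Series(values, index=labels.astype(int), name="dice")


def binarized_difference_sum(pairs) -> np.ndarray:
    """Per-voxel count of pairs whose segmentations disagree at that voxel.

    ``pairs`` is a sequence of (mask, mask) — typically one pair per
    subject, the two conditions' segmentations.  The result is an
    integer grid bounded above by the number of pairs.
    """
    total: np.ndarray | None = None
    for a, b in pairs:
        ma, mb = _as_mask(a), _as_mask(b)
        if ma.shape != mb.shape:
            raise ValueError(f"grid shapes differ: {ma.shape} vs {mb.shape}")
        diff = (ma.data != mb.data).astype(np.int64)
        if total is None:
            total = diff
        elif total.shape != diff.shape:
            raise ValueError(
                f"grid shapes differ across pairs: {total.shape} vs {diff.shape}"
            )
        else:
            total = total + diff
    if total is None:
        raise ValueError("at least one pair of masks is required")
    return total
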