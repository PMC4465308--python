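"""Read, write and clean fingerprint band data.

A fingerprint ("band profile") is a multiset of integer band sizes in base
pairs.  Files use a minimal plain-text dialect: an optional ``#`` comment
header, then per clone a ``>clone_id`` line followed by one line of
whitespace-separated integer band sizes (empty line for an empty profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

BAND_MIN = 50
BAND_MAX = 500

__all__ = [
    "BAND_MIN",
    "BAND_MAX",
    "BandProfile",
    "FingerprintSet",
    "FilterReport",
    "read_band_file",
    "write_band_file",
    "filter_bands",
]


@dataclass(frozen=True)
class BandProfile:
    """A clone's fingerprint: a sorted multiset of integer band sizes."""

    clone_id: str
    bands: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(sorted(int(b) for b in self.bands)))

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def empty(self) -> bool:
        return not self.bands


@dataclass
class FingerprintSet:
    """Band profiles keyed by clone id, with a provenance note."""

    profiles: dict[str, BandProfile] = field(default_factory=dict)
    provenance: str = ""

    def add(self, profile: BandProfile) -> None:
        if profile.clone_id in self.profiles:
            raise ValueError(f"duplicate clone id: {profile.clone_id}")
        self.profiles[profile.clone_id] = profile

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[BandProfile]:
        return iter(self.profiles.values())

    def __getitem__(self, clone_id: str) -> BandProfile:
        return self.profiles[clone_id]

    def __contains__(self, clone_id: str) -> bool:
        return clone_id in self.profiles

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FingerprintSet):
            return NotImplemented
        return self.profiles == other.profiles

    @property
    def clone_ids(self) -> list[str]:
        return list(self.profiles)

    @classmethod
    def from_profiles(cls, profiles: Iterable[BandProfile], provenance: str = "") -> "FingerprintSet":
        fset = cls(provenance=provenance)
        for p in profiles:
            fset.add(p)
        return fset


def write_band_file(fset: FingerprintSet, path: str | Path) -> None:
    """Write a fingerprint set in the plain-text band dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# bands\t{fset.provenance}\n")
        for profile in fset:
            fh.write(f">{profile.clone_id}\n")
            fh.write(" ".join(str(b) for b in profile.bands) + "\n")


def read_band_file(path: str | Path) -> FingerprintSet:
    """Parse a band file; malformed records raise with the offending line number."""
    path = Path(path)
    fset = FingerprintSet(provenance=str(path))
    lines = path.read_text().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if not line.strip() or line.startswith("#"):
            i += 1
            continue
        if not line.startswith(">"):
            raise ValueError(f"{path}:{i + 1}: expected '>clone_id' header, got {line!r}")
        clone_id = line[1:].strip()
        if not clone_id:
            raise ValueError(f"{path}:{i + 1}: empty clone id")
        if i + 1 >= n:
            raise ValueError(f"{path}:{i + 1}: truncated record for {clone_id!r}")
        band_line = lines[i + 1]
        try:
            bands = tuple(int(tok) for tok in band_line.split())
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 2}: non-integer band size in {band_line!r}") from exc
        if clone_id in fset:
            raise ValueError(f"{path}:{i + 1}: duplicate clone id {clone_id!r}")
        fset.add(BandProfile(clone_id, bands))
        i += 2
    return fset


@dataclass
class FilterReport:
    """Per-clone rejection record produced by :func:`filter_bands`."""

    retained: int
    dropped: int
    dropped_clones: list[tuple[str, str]] = field(default_factory=list)
    bands_removed: int = 0

    @property
    def total(self) -> int:
        return self.retained + self.dropped

    @property
    def retained_fraction(self) -> float:
        return self.retained / self.total if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped_clones, columns=["clone_id", "reason"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_bands(
    fset: FingerprintSet,
    min_size: int = BAND_MIN,
    max_size: int = BAND_MAX,
    min_band_count: int = 5,
) -> tuple[FingerprintSet, FilterReport]:
    """Drop out-of-range bands, then drop poor-quality profiles.

    Bands outside ``[min_size, max_size]`` are removed; profiles left with
    fewer than ``min_band_count`` bands are dropped and listed in the report.
    Filtering is idempotent.
    """
    if min_size > max_size:
        raise ValueError(f"min_size {min_size} > max_size {max_size}")
    out = FingerprintSet(provenance=fset.provenance)
    report = FilterReport(retained=0, dropped=0)
    for profile in fset:
        kept = tuple(b for b in profile.bands if min_size <= b <= max_size)
        report.bands_removed += profile.n_bands - len(kept)
        if len(kept) < min_band_count:
            report.dropped += 1
            report.dropped_clones.append((profile.clone_id, "too_few_bands"))
            continue
        report.retained += 1
        out.add(BandProfile(profile.clone_id, kept))
    return out, report
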