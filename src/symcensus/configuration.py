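"""Backtracking, per-subunit labels, necklace canonicalization and census.

A symmetry-expanded, focused-classified particle table holds n records per
parent oligomer, one per subunit slot.  Backtracking regroups those records
by parent; reading each record's class number through a user-supplied class
map yields an ordered label vector over a small alphabet (canonically
{i, o}: inward/outward conformation of the classified subunit feature).

Because consensus refinement under Cn leaves each particle's orientation
defined only up to an unknown symmetry operator, the label vector of one
particle is observed up to cyclic rotation.  The rotation-invariant object
is the *necklace* — the equivalence class of the label string under cyclic
rotation — represented here by its canonical form: the lexicographically
smallest rotation (alphabet order i < o, i.e. plain string order).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .star import ParticleTable, require_columns
from .symmetry import SUBUNIT_INDEX_TAG, normalize_angle

__all__ = [
    "EXCLUDED",
    "PARENT_KEY_TAGS",
    "CLASS_TAG",
    "SubunitLabelVector",
    "Configuration",
    "ConfigurationCensus",
    "ParentGroup",
    "BacktrackError",
    "ClassMapError",
    "backtrack_parents",
    "read_labels",
    "rotate_string",
    "canonical_form",
    "enumerate_configurations",
    "necklace_count",
    "census",
    "parse_class_map",
]

#: Sentinel label for classes whose subunits are unresolved; a parent with
#: any excluded subunit is dropped whole from the census.
EXCLUDED = "excluded"

#: Columns identifying a parent particle; expanded copies duplicate them verbatim.
PARENT_KEY_TAGS = (
    "_rlnMicrographName",
    "_rlnImageName",
    "_rlnCoordinateX",
    "_rlnCoordinateY",
)

CLASS_TAG = "_rlnClassNumber"


class BacktrackError(Exception):
    """Raised for parents whose expanded records are inconsistent."""


class ClassMapError(Exception):
    """Raised when a class number has no entry in the class map."""


@dataclass(frozen=True)
class SubunitLabelVector:
    """Ordered per-subunit state labels for one oligomer."""

    labels: tuple[str, ...]
    parent_key: tuple = ()

    @property
    def excluded(self) -> bool:
        return EXCLUDED in self.labels

    def as_string(self) -> str:
        if self.excluded:
            raise ValueError("label vector contains excluded subunits")
        return "".join(self.labels)


@dataclass(frozen=True)
class Configuration:
    """A cyclic configuration: canonical necklace string plus how to reach it.

    ``shift`` is the smallest r in [0, n) with rotate(observed, r) ==
    canonical, where rotate(s, r)[j] = s[(j + r) mod n].  ``period`` is the
    smallest p > 0 with rotate(canonical, p) == canonical (n for aperiodic
    strings, 1 for uniform ones; for prime n no other value occurs).
    """

    canonical: str
    shift: int
    period: int

    @property
    def n(self) -> int:
        return len(self.canonical)


@dataclass
class ParentGroup:
    """The n expanded records of one parent, ordered by subunit index."""

    key: tuple
    records: pd.DataFrame  # n rows, in subunit-index order 0..n-1

    def class_numbers(self) -> list:
        return list(self.records[CLASS_TAG])


@dataclass
class ConfigurationCensus:
    """Counts and frequencies of cyclic configurations over a particle set."""

    counts: dict[str, int] = field(default_factory=dict)
    excluded_count: int = 0

    @property
    def included_total(self) -> int:
        return sum(self.counts.values())

    @property
    def particle_frequencies(self) -> dict[str, float]:
        total = self.included_total
        if total == 0:
            return {c: 0.0 for c in self.counts}
        return {c: k / total for c, k in self.counts.items()}

    @property
    def subunit_fraction(self) -> dict[str, float]:
        """Fraction of subunits per label, over included parents."""
        tally: Counter[str] = Counter()
        for config, k in self.counts.items():
            for ch in config:
                tally[ch] += k
        total = sum(tally.values())
        if total == 0:
            return {}
        return {lab: v / total for lab, v in sorted(tally.items())}

    def to_frame(self) -> pd.DataFrame:
        freqs = self.particle_frequencies
        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            {
                "configuration": [c for c, _ in rows],
                "count": [k for _, k in rows],
                "frequency": [freqs[c] for c, _ in rows],
            }
        )


def _recover_subunit_indices(rot: np.ndarray, n: int) -> np.ndarray:
    """Recover copy indices from rot offsets relative to the group's first record.

    Fallback for externally expanded tables that lack the stored copy-index
    column; relies on expansion emitting the untouched parent record first.
    """
    step = 360.0 / n
    delta = normalize_angle(np.asarray(rot, dtype=float) - float(rot[0]))
    k = np.rint(np.mod(delta, 360.0) / step).astype(np.int64) % n
    return k


def backtrack_parents(
    expanded: ParticleTable, n: int, strict: bool = False
) -> tuple[list[ParentGroup], list[tuple]]:
    """Regroup symmetry-expanded records by their parent particle.

    Parents are identified by (micrograph name, image name, x, y) exactly as
    read.  Groups come back in first-appearance order, each with exactly n
    records carrying distinct subunit indices 0..n-1.

    Returns ``(groups, incomplete)`` where ``incomplete`` lists the keys of
    parents with a record count other than n (raised instead if ``strict``).
    A duplicated subunit index within a parent is always an error.
    """
    require_columns(expanded, PARENT_KEY_TAGS)
    df = expanded.df

    has_index_col = SUBUNIT_INDEX_TAG in df.columns
    groups: list[ParentGroup] = []
    incomplete: list[tuple] = []

    for key, sub in df.groupby(list(PARENT_KEY_TAGS), sort=False):
        if len(sub) != n:
            if strict:
                raise BacktrackError(
                    f"parent {key} has {len(sub)} records, expected {n}"
                )
            incomplete.append(key)
            continue
        if has_index_col:
            k = sub[SUBUNIT_INDEX_TAG].to_numpy(dtype=np.int64)
        else:
            k = _recover_subunit_indices(sub["_rlnAngleRot"].to_numpy(), n)
        if len(np.unique(k)) != n:
            raise BacktrackError(f"parent {key} has duplicate subunit indices")
        ordered = sub.iloc[np.argsort(k, kind="stable")]
        groups.append(ParentGroup(key=key, records=ordered))
    return groups, incomplete


def read_labels(
    group: ParentGroup, class_map: Mapping[int, str]
) -> SubunitLabelVector:
    """Map a parent's class numbers to subunit labels, in subunit-index order.

    ``class_map`` maps focused-classification class numbers to state labels,
    or to :data:`EXCLUDED` for classes whose feature was unresolved.
    """
    labels = []
    for c in group.class_numbers():
        c = int(c)
        if c not in class_map:
            raise ClassMapError(f"class number {c} not present in class map")
        labels.append(class_map[c])
    return SubunitLabelVector(labels=tuple(labels), parent_key=group.key)


def rotate_string(s: str, r: int) -> str:
    """Cyclic rotation: rotate(s, r)[j] = s[(j + r) mod n]."""
    n = len(s)
    r %= n
    return s[r:] + s[:r]


def canonical_form(labels: SubunitLabelVector | str) -> Configuration:
    """Canonicalize a cyclic label string to its necklace representative.

    The canonical form is the lexicographically smallest of the n rotations
    (plain string order, so i < o); ``shift`` is the smallest rotation
    achieving it.  Rotations only — no reflection: particle handedness is
    physically fixed, so mirror-related arrangements (e.g. iioio vs ioioo)
    are distinct configurations.
    """
    s = labels if isinstance(labels, str) else labels.as_string()
    n = len(s)
    if n == 0:
        raise ValueError("empty label string")
    rotations = [rotate_string(s, r) for r in range(n)]
    canonical = min(rotations)
    shift = rotations.index(canonical)
    period = next(
        p for p in range(1, n + 1) if rotate_string(canonical, p) == canonical
    )
    return Configuration(canonical=canonical, shift=shift, period=period)


def enumerate_configurations(n: int, alphabet: Iterable[str]) -> list[str]:
    """All distinct canonical configurations of length n, sorted.

    Brute force over |alphabet|^n strings; the count matches the
    necklace-counting formula (1/n) * sum_{d|n} phi(d) * |alphabet|^(n/d).
    """
    alphabet = sorted(set(alphabet))
    if n < 1:
        raise ValueError("n must be >= 1")
    if not alphabet:
        raise ValueError("alphabet must be nonempty")
    seen = {canonical_form("".join(t)).canonical for t in product(alphabet, repeat=n)}
    return sorted(seen)


def _totient(d: int) -> int:
    result, m, p = d, d, 2
    while p * p <= m:
        if m % p == 0:
            while m % p == 0:
                m //= p
            result -= result // p
        p += 1
    if m > 1:
        result -= result // m
    return result


def necklace_count(n: int, alphabet_size: int) -> int:
    """Number of necklaces of length n over an alphabet of the given size
    (Burnside: (1/n) * sum over d | n of phi(d) * a^(n/d))."""
    total = sum(
        _totient(d) * alphabet_size ** (n // d) for d in range(1, n + 1) if n % d == 0
    )
    return total // n


def census(
    configs: Sequence[Configuration], excluded: int = 0
) -> ConfigurationCensus:
    """Tally canonical configurations over a set of parents."""
    counts: dict[str, int] = {}
    for c in configs:
        counts[c.canonical] = counts.get(c.canonical, 0) + 1
    return ConfigurationCensus(counts=counts, excluded_count=excluded)


def parse_class_map(spec: str) -> dict[int, str]:
    """Parse a ``label=class[,class...]`` mapping string, e.g. ``i=1,o=2`` or
    ``i=1,o=2,excluded=3,4``."""
    mapping: dict[int, str] = {}
    label = None
    for chunk in spec.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            label, _, val = chunk.partition("=")
            label = label.strip()
        else:
            val = chunk
        if label is None:
            raise ValueError(f"class map entry {chunk!r} has no label")
        mapping[int(val)] = label
    return mapping


def census_from_table(
    expanded: ParticleTable, class_map: Mapping[int, str], n: int
) -> ConfigurationCensus:
    """Full pipeline: backtrack -> labels -> canonicalize -> census."""
    groups, incomplete = backtrack_parents(expanded, n)
    excluded = len(incomplete)
    configs = []
    for g in groups:
        vec = read_labels(g, class_map)
        if vec.excluded:
            excluded += 1
            continue
        configs.append(canonical_form(vec))
    return census(configs, excluded=excluded)


__all__.append("census_from_table")
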