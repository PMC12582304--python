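"""Supervised particle reorientation.

After consensus refinement under Cn, same-configuration particles sit in
arbitrary symmetry-related frames, so averaging them directly washes out any
asymmetric feature.  Reorientation composes each parent's orientation with
the cyclic operator given by its configuration's canonicalizing shift: the
subunit-label readout of every reoriented particle then equals the canonical
string slot for slot, and particles of one configuration share a reference
frame.  Reconstruction downstream needs no further alignment.

Only orientation metadata is touched — rot changes by shift*360/n, image
pixels and all other columns are untouched (origin shifts are unaffected by
a rotation about the projection normal under the stated convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .configuration import (
    Configuration,
    backtrack_parents,
    canonical_form,
    read_labels,
)
from .star import ParticleTable
from .symmetry import SUBUNIT_INDEX_TAG, EulerTriple, compose_with_operator

__all__ = ["ReorientedAssignment", "reorient_particle", "emit_configuration_tables"]


@dataclass(frozen=True)
class ReorientedAssignment:
    """One parent particle's reoriented pose and its configuration."""

    parent_key: tuple
    configuration: Configuration
    new_orientation: EulerTriple


def reorient_particle(
    parent_orientation: EulerTriple, config: Configuration, n: int
) -> ReorientedAssignment:
    """Compose a parent orientation with its configuration's shift operator.

    Equivalently one may *select* the expanded copy whose subunit index
    equals the shift — under the stated convention both give the same rot.
    """
    if not 0 <= config.shift < n:
        raise ValueError(f"shift {config.shift} outside [0, {n})")
    return ReorientedAssignment(
        parent_key=(),
        configuration=config,
        new_orientation=compose_with_operator(parent_orientation, config.shift, n),
    )


def emit_configuration_tables(
    expanded: ParticleTable, class_map: Mapping[int, str], n: int
) -> tuple[dict[str, ParticleTable], int]:
    """Group parents by configuration and reorient each into its canonical frame.

    Returns ``(tables, excluded_count)``: one table per observed
    configuration, each holding exactly one reoriented record per parent
    (the consensus record with rot updated; non-angle columns copied from
    the parent).  Parents with any excluded subunit, and incomplete parents,
    are counted in ``excluded_count``.  Conservation: the record counts over
    all tables plus ``excluded_count`` equal the parent count.
    """
    groups, incomplete = backtrack_parents(expanded, n)
    excluded = len(incomplete)

    rows_by_config: dict[str, list] = {}
    for g in groups:
        vec = read_labels(g, class_map)
        if vec.excluded:
            excluded += 1
            continue
        config = canonical_form(vec)
        parent_row = g.records.iloc[0].copy()  # copy k=0 == original record
        e = EulerTriple(
            float(parent_row["_rlnAngleRot"]),
            float(parent_row["_rlnAngleTilt"]),
            float(parent_row["_rlnAnglePsi"]),
        )
        assignment = reorient_particle(e, config, n)
        parent_row["_rlnAngleRot"] = assignment.new_orientation.rot
        rows_by_config.setdefault(config.canonical, []).append(parent_row)

    tables: dict[str, ParticleTable] = {}
    for name, rows in rows_by_config.items():
        out = expanded.copy()
        df = pd.DataFrame(rows).reset_index(drop=True)
        df = df[list(expanded.df.columns)]
        for c in df.columns:  # restore dtypes lost through per-row Series
            try:
                df[c] = df[c].astype(expanded.df[c].dtype)
            except (TypeError, ValueError):
                pass
        if SUBUNIT_INDEX_TAG in df.columns:
            df = df.drop(columns=[SUBUNIT_INDEX_TAG])
        out.df = df
        tables[name] = out
    return tables, excluded
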