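"""Resolve what a figure shows: window, markers in scope, lead SNP, significance.

A plot scope is either a chromosomal region (chrom + left/right borders) or a
transcript window optionally extended by strand-aware 5'/3' flanks.  Windows
are closed intervals; the significance comparison -log10(p) >= threshold is
inclusive.
"""

from __future__ import annotations

import difflib
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Union

import pandas as pd

from .formats_io import AnnotationSet, AssociationTable, TranscriptModel

__all__ = [
    "RegionSpec",
    "GenicSpec",
    "PlotScope",
    "EmptyScopeError",
    "resolve_region",
    "resolve_genic",
    "neglog10",
    "find_lead",
    "filter_significant",
]

# absorbs float rounding at exact -log10 boundaries (e.g. p = 1e-5 vs 5.0)
_BOUNDARY_EPS = 1e-12


class EmptyScopeError(ValueError):
    """No association markers fall inside the requested window."""


@dataclass(frozen=True)
class RegionSpec:
    """A chromosomal window [left, right], closed, 1-based."""

    chrom: str
    left: int
    right: int

    def __post_init__(self):
        if self.left >= self.right:
            raise ValueError(
                f"region left ({self.left}) must be < right ({self.right})"
            )
        if self.left < 1:
            raise ValueError(f"region left must be >= 1, got {self.left}")

    @property
    def width(self) -> int:
        return self.right - self.left


@dataclass(frozen=True)
class GenicSpec:
    """A transcript window extended by up/down basepairs of flank.

    ``up`` extends the 5' (upstream/promoter) side and ``down`` the 3' side,
    so on the minus strand ``up`` grows the genomic *right* edge.
    """

    transcript_id: str
    up: int = 0
    down: int = 0

    def __post_init__(self):
        if self.up < 0 or self.down < 0:
            raise ValueError("flank lengths up/down must be >= 0")


class Lead(NamedTuple):
    marker: str
    chrom: str
    pos: int
    p: float


@dataclass
class PlotScope:
    """Everything resolved for one figure: window, rows, genes, lead, threshold."""

    region: RegionSpec
    assoc: pd.DataFrame                      # marker chrom pos p, position order
    genes: list = field(default_factory=list)
    transcripts: list = field(default_factory=list)
    focal_transcript: Optional[TranscriptModel] = None
    threshold: Optional[float] = None
    lead: Optional[Lead] = None
    significant: Optional[set] = None

    @property
    def marker_names(self) -> set:
        return set(self.assoc["marker"])


def neglog10(p: float) -> float:
    """-log10(p) for p in (0, 1]."""
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return max(0.0, -math.log10(p))


def resolve_region(assoc: AssociationTable, ann: AnnotationSet,
                   spec: RegionSpec) -> PlotScope:
    """Select association rows and gene models for a chromosomal window.

    Rows need chrom equality and left <= pos <= right; gene models qualify by
    overlapping the window at one basepair or more.
    """
    df = assoc.table
    sel = df[(df["chrom"] == str(spec.chrom))
             & (df["pos"] >= spec.left) & (df["pos"] <= spec.right)]
    if len(sel) == 0:
        raise EmptyScopeError(
            f"no association markers on chrom {spec.chrom} in "
            f"[{spec.left}, {spec.right}]; try a wider window"
        )
    return PlotScope(
        region=spec,
        assoc=sel.reset_index(drop=True),
        genes=ann.genes_overlapping(spec.chrom, spec.left, spec.right),
        transcripts=ann.transcripts_overlapping(spec.chrom, spec.left, spec.right),
    )


def resolve_genic(assoc: AssociationTable, ann: AnnotationSet,
                  spec: GenicSpec) -> PlotScope:
    """Resolve a transcript-centred window with strand-aware flanks."""
    tx = ann.transcripts.get(spec.transcript_id)
    if tx is None:
        near = difflib.get_close_matches(
            spec.transcript_id, list(ann.transcripts), n=5, cutoff=0.0
        )
        raise LookupError(
            f"transcript {spec.transcript_id!r} not found in annotation; "
            f"nearest ids: {near}"
        )
    if tx.strand == "+":
        left = tx.start - spec.up
        right = tx.end + spec.down
    else:
        left = tx.start - spec.down
        right = tx.end + spec.up
    region = RegionSpec(tx.chrom, max(1, left), right)
    scope = resolve_region(assoc, ann, region)
    scope.focal_transcript = tx
    return scope


def find_lead(scope: PlotScope,
              user_snp: Optional[Union[str, tuple]] = None) -> Lead:
    """The lead SNP: the user's choice if given, else the smallest p.

    Ties at the minimum p break by smallest position, then lexical marker
    name, so the result is independent of input row order.
    """
    df = scope.assoc
    if len(df) == 0:
        raise EmptyScopeError("scope holds no markers")
    if user_snp is not None:
        if isinstance(user_snp, str):
            hit = df[df["marker"] == user_snp]
        else:
            chrom, pos = user_snp
            hit = df[(df["chrom"] == str(chrom)) & (df["pos"] == int(pos))]
        if len(hit) == 0:
            raise LookupError(f"requested lead SNP {user_snp!r} is not in scope")
        row = hit.iloc[0]
    else:
        row = df.sort_values(["p", "pos", "marker"], kind="mergesort").iloc[0]
    return Lead(str(row["marker"]), str(row["chrom"]), int(row["pos"]),
                float(row["p"]))


def filter_significant(scope: PlotScope, threshold: float) -> set:
    """Marker names with -log10(p) >= threshold (inclusive boundary)."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    df = scope.assoc
    keep = df["p"].map(neglog10) >= threshold - _BOUNDARY_EPS
    return set(df.loc[keep, "marker"])
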