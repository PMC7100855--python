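"""Readers and writers for the three input formats.

Genotypes come in as HapMap text (11 fixed metadata columns followed by one
column of diploid calls per sample), gene models as GTF, and association
results as a delimited table with remappable column names.  Pairwise LD
estimates can be exported as a tab-separated table.

All genomic coordinates are 1-based and intervals are fully closed.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

__all__ = [
    "FormatError",
    "ColumnMappingError",
    "MarkerMeta",
    "GenotypeMatrix",
    "LoadReport",
    "AssociationTable",
    "TranscriptModel",
    "GeneModel",
    "AnnotationSet",
    "read_hapmap",
    "read_gtf",
    "read_association",
    "write_ld_table",
    "write_hapmap",
    "write_association",
    "write_gtf",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ColumnMappingError(FormatError):
    """Raised when a configured column name cannot be resolved in a header."""


#: The 11 fixed metadata columns of the HapMap genotype text format.
HAPMAP_COLUMNS = (
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
)

_MISSING_CALLS = {"NN", "N", "--", "", "NA", ".", ".."}

# IUPAC single-letter diploid codes (heterozygotes as ambiguity codes).
_IUPAC = {
    "A": ("A", "A"), "C": ("C", "C"), "G": ("G", "G"), "T": ("T", "T"),
    "R": ("A", "G"), "Y": ("C", "T"), "S": ("C", "G"), "W": ("A", "T"),
    "K": ("G", "T"), "M": ("A", "C"),
}


def _chrom_key(chrom: str):
    """Sort key giving numeric chromosomes natural order before others."""
    s = str(chrom)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)


@dataclass(frozen=True)
class MarkerMeta:
    """Identity and observed alleles of one biallelic marker.

    ``minor``/``major`` record which observed allele the dosage counts;
    for a monomorphic marker ``minor`` is ``None`` and all dosages are 0.
    """

    name: str
    chrom: str
    pos: int
    alleles: frozenset = frozenset()
    minor: Optional[str] = None
    major: Optional[str] = None

    def __post_init__(self):
        if not self.name:
            raise ValueError("marker name must be non-empty")
        if not str(self.chrom):
            raise ValueError("marker chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"marker pos must be >= 1, got {self.pos}")


@dataclass
class LoadReport:
    """Bookkeeping for a genotype load: every input row is retained or dropped."""

    n_rows: int = 0
    n_retained: int = 0
    n_dropped_non_biallelic: int = 0
    n_dropped_no_calls: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_non_biallelic + self.n_dropped_no_calls


@dataclass
class GenotypeMatrix:
    """Unphased diploid genotypes as minor-allele dosages.

    ``dosages`` is a float array of shape (n_markers, n_samples) holding
    values in {0, 1, 2} with ``nan`` for missing calls.  Markers are sorted
    by (chrom, pos).
    """

    markers: list
    samples: list
    dosages: np.ndarray
    report: LoadReport = field(default_factory=LoadReport)
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.markers), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def positions(self) -> np.ndarray:
        return np.array([m.pos for m in self.markers], dtype=np.int64)

    def index_of(self, chrom: str, pos: int) -> Optional[int]:
        """Index of the marker at (chrom, pos), or None."""
        if self._index is None:
            object.__setattr__(
                self, "_index",
                {(str(m.chrom), m.pos): k for k, m in enumerate(self.markers)},
            )
        return self._index.get((str(chrom), int(pos)))

    def markers_in_region(self, chrom: str, left: int, right: int) -> list:
        """Indices of markers on ``chrom`` with left <= pos <= right."""
        return [
            k for k, m in enumerate(self.markers)
            if str(m.chrom) == str(chrom) and left <= m.pos <= right
        ]

    def subset(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            markers=[self.markers[k] for k in idx],
            samples=list(self.samples),
            dosages=self.dosages[idx],
            report=self.report,
        )


@dataclass
class AssociationTable:
    """Per-marker GWAS results: marker, chrom, pos, p, sorted by (chrom, pos)."""

    table: pd.DataFrame
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TranscriptModel:
    """One transcript: strand plus its exon/CDS/UTR intervals (1-based, closed)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    features: list  # list of (kind, start, end)

    @property
    def start(self) -> int:
        return min(s for _, s, _ in self.features)

    @property
    def end(self) -> int:
        return max(e for _, _, e in self.features)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcript_ids: list


@dataclass
class AnnotationSet:
    """Transcript models keyed by id, plus gene spans as the union of transcripts."""

    transcripts: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)

    def genes_overlapping(self, chrom: str, left: int, right: int) -> list:
        return [
            g for g in self.genes.values()
            if str(g.chrom) == str(chrom) and g.start <= right and g.end >= left
        ]

    def transcripts_overlapping(self, chrom: str, left: int, right: int) -> list:
        return [
            t for t in self.transcripts.values()
            if str(t.chrom) == str(chrom) and t.start <= right and t.end >= left
        ]


# ---------------------------------------------------------------------------
# genotype canonicalization (shared by the HapMap reader and the simulator)

def _canonical_marker(name, chrom, pos, calls):
    """Turn decoded allele-pair calls into a (MarkerMeta, dosage) pair.

    Returns None for markers that must be dropped (no informative calls, or
    more than two observed alleles).  The minor allele is the empirically less
    frequent one; ties break to the alphabetically first allele.
    """
    counts = Counter()
    for c in calls:
        if c is not None:
            counts[c[0]] += 1
            counts[c[1]] += 1
    if not counts:
        return None, "no_calls"
    alleles = sorted(counts)
    if len(alleles) > 2:
        return None, "non_biallelic"
    if len(alleles) == 2:
        a, b = alleles  # alphabetical; tie on count -> a is minor
        minor, major = (a, b) if counts[a] <= counts[b] else (b, a)
    else:
        minor, major = None, alleles[0]
    dos = np.full(len(calls), np.nan)
    for k, c in enumerate(calls):
        if c is None:
            continue
        if minor is None:
            dos[k] = 0.0
        else:
            dos[k] = float((c[0] == minor) + (c[1] == minor))
    meta = MarkerMeta(str(name), str(chrom), int(pos),
                      frozenset(alleles), minor=minor, major=major)
    return (meta, dos), None


def genotype_matrix_from_calls(names, chroms, positions, calls, samples,
                               ) -> GenotypeMatrix:
    """Build a GenotypeMatrix from decoded per-marker allele-pair calls.

    ``calls`` is an iterable of per-marker lists of (allele, allele) tuples or
    None for missing.  Markers are canonicalized (empirical minor allele) and
    sorted by (chrom, pos); non-biallelic / fully-missing markers are dropped
    and counted in the report.
    """
    report = LoadReport()
    entries = []
    for name, chrom, pos, row in zip(names, chroms, positions, calls):
        report.n_rows += 1
        result, reason = _canonical_marker(name, chrom, pos, row)
        if result is None:
            if reason == "no_calls":
                report.n_dropped_no_calls += 1
            else:
                report.n_dropped_non_biallelic += 1
            continue
        entries.append(result)
    report.n_retained = len(entries)
    entries.sort(key=lambda e: (_chrom_key(e[0].chrom), e[0].pos))
    markers = [e[0] for e in entries]
    if entries:
        dosages = np.vstack([e[1] for e in entries])
    else:
        dosages = np.empty((0, len(samples)))
    return GenotypeMatrix(markers=markers, samples=list(samples),
                          dosages=dosages, report=report)


# ---------------------------------------------------------------------------
# HapMap reader

def _decode_call(token: str, dialect: str):
    tok = token.strip()
    if tok.upper() in _MISSING_CALLS:
        return None
    if dialect == "iupac":
        return _IUPAC.get(tok.upper())
    if len(tok) == 2:
        return (tok[0].upper(), tok[1].upper())
    return None


def _detect_dialect(call_tokens) -> str:
    widths = {len(t.strip()) for t in call_tokens
              if t.strip().upper() not in _MISSING_CALLS}
    if widths and widths <= {1}:
        return "iupac"
    return "two-letter"


def read_hapmap(path: PathLike, dialect: str = "auto") -> GenotypeMatrix:
    """Read a HapMap genotype text file into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        Tab-separated file with the 11 fixed HapMap metadata columns followed
        by one column per sample.
    dialect
        ``"two-letter"`` for calls like ``"AG"``, ``"iupac"`` for single-letter
        ambiguity codes (``"R"`` = A/G het), or ``"auto"`` to detect from the
        first data row.

    Markers with more than two observed alleles or with zero non-missing calls
    are dropped and counted in ``GenotypeMatrix.report``.  ``NN``/``N``/``--``
    map to missing.  Output is sorted by (chrom, pos).
    """
    if dialect not in {"two-letter", "iupac", "auto"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        if len(header) < 12:
            raise FormatError(
                f"{path}: HapMap header needs >= 12 tab-separated columns "
                f"(11 metadata + samples), found {len(header)}"
            )
        for want, got in zip(HAPMAP_COLUMNS, header):
            if got.strip().lower() != want.lower():
                raise FormatError(
                    f"{path}: malformed HapMap header: expected column "
                    f"{want!r}, found {got!r}"
                )
        samples = [h.strip() for h in header[11:]]

        names, chroms, positions, all_calls = [], [], [], []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"found {len(fields)}"
                )
            try:
                pos = int(fields[3])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer pos {fields[3]!r}"
                ) from None
            tokens = fields[11:]
            if dialect == "auto":
                dialect = _detect_dialect(tokens)
            names.append(fields[0])
            chroms.append(fields[2])
            positions.append(pos)
            all_calls.append([_decode_call(t, dialect) for t in tokens])

    return genotype_matrix_from_calls(names, chroms, positions, all_calls,
                                      samples)


# ---------------------------------------------------------------------------
# GTF reader

_FEATURE_KINDS = {
    "exon": "exon",
    "cds": "CDS",
    "five_prime_utr": "five_prime_UTR",
    "5utr": "five_prime_UTR",
    "three_prime_utr": "three_prime_UTR",
    "3utr": "three_prime_UTR",
}


def read_gtf(path: PathLike) -> AnnotationSet:
    """Parse a GTF file into an :class:`AnnotationSet`.

    Only exon/CDS/UTR rows contribute features; unknown feature kinds are
    ignored.  Rows lacking a ``transcript_id`` attribute are skipped with a
    warning.  Gene spans are the union of their transcripts' spans.
    """
    path = Path(path)
    transcripts: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                warnings.warn(f"{path}:{lineno}: not 9 columns; skipped")
                continue
            kind = _FEATURE_KINDS.get(cols[2].lower())
            if kind is None:
                continue
            try:
                feat = feature_from_line(line)
            except Exception:
                warnings.warn(f"{path}:{lineno}: unparseable feature; skipped")
                continue
            start, end = feat.start, feat.end
            if start is None or end is None or start > end:
                warnings.warn(f"{path}:{lineno}: invalid interval; skipped")
                continue
            if feat.strand not in {"+", "-"}:
                warnings.warn(f"{path}:{lineno}: strand must be +/-; skipped")
                continue
            tid = (feat.attributes.get("transcript_id") or [None])[0]
            gid = (feat.attributes.get("gene_id") or [None])[0]
            if not tid:
                warnings.warn(
                    f"{path}:{lineno}: {kind} row missing transcript_id; skipped"
                )
                continue
            if not gid:
                gid = tid
            tx = transcripts.get(tid)
            if tx is None:
                tx = TranscriptModel(tid, gid, str(feat.seqid), feat.strand, [])
                transcripts[tid] = tx
            elif str(feat.seqid) != tx.chrom:
                warnings.warn(
                    f"{path}:{lineno}: feature on {feat.seqid} but transcript "
                    f"{tid} is on {tx.chrom}; skipped"
                )
                continue
            tx.features.append((kind, int(start), int(end)))

    genes: dict = {}
    for tid, tx in transcripts.items():
        g = genes.get(tx.gene_id)
        if g is None:
            genes[tx.gene_id] = GeneModel(
                tx.gene_id, tx.chrom, tx.start, tx.end, tx.strand, [tid]
            )
        else:
            g.start = min(g.start, tx.start)
            g.end = max(g.end, tx.end)
            g.transcript_ids.append(tid)
    return AnnotationSet(transcripts=transcripts, genes=genes)


# ---------------------------------------------------------------------------
# association table reader

DEFAULT_COLUMN_MAP = {"marker": "Marker", "chrom": "Locus", "pos": "Site", "p": "p"}


def read_association(path: PathLike,
                     column_map: Optional[Mapping[str, str]] = None,
                     ) -> AssociationTable:
    """Read a delimited association-results table.

    ``column_map`` maps the roles ``marker``/``chrom``/``pos``/``p`` to the
    file's column names (defaults are TASSEL-style: Marker/Locus/Site/p).
    Rows with p outside (0, 1] or a non-numeric position are dropped and
    counted; duplicate (chrom, pos) rows keep the first occurrence.  The
    result is sorted by (chrom, pos).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=None, engine="python")
    for role, col in cmap.items():
        if col not in df.columns:
            raise ColumnMappingError(
                f"{path}: no column {col!r} for role {role!r}; "
                f"available headers: {list(df.columns)}"
            )
    out = pd.DataFrame({
        "marker": df[cmap["marker"]].astype(str),
        "chrom": df[cmap["chrom"]].astype(str).str.strip(),
        "pos": pd.to_numeric(df[cmap["pos"]], errors="coerce"),
        "p": pd.to_numeric(df[cmap["p"]], errors="coerce"),
    })
    n0 = len(out)
    keep = out["pos"].notna() & out["p"].notna() & (out["p"] > 0) & (out["p"] <= 1)
    out = out[keep].copy()
    out["pos"] = out["pos"].astype(np.int64)
    out = out.drop_duplicates(subset=["chrom", "pos"], keep="first")
    n_dropped = n0 - len(out)
    out = out.sort_values(
        ["chrom", "pos"],
        key=lambda s: s.map(_chrom_key) if s.name == "chrom" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return AssociationTable(table=out, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# writers

def write_ld_table(results: Iterable, path: PathLike) -> Path:
    """Write LD results as TSV: markerA markerB chromA posA chromB posB r2 Dprime n.

    Floats are written at 6 decimals; pairs whose status is not ``ok`` get NA
    in the value columns.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("markerA\tmarkerB\tchromA\tposA\tchromB\tposB\tr2\tDprime\tn\n")
        for r in results:
            if r.status == "ok":
                r2, dp = f"{r.r2:.6f}", f"{r.Dprime:.6f}"
            else:
                r2, dp = "NA", "NA"
            n = r.freqs.n_used if r.freqs is not None else 0
            fh.write(
                f"{r.marker_i.name}\t{r.marker_j.name}\t"
                f"{r.marker_i.chrom}\t{r.marker_i.pos}\t"
                f"{r.marker_j.chrom}\t{r.marker_j.pos}\t{r2}\t{dp}\t{n}\n"
            )
    return path


def write_hapmap(gt: GenotypeMatrix, path: PathLike) -> Path:
    """Write a GenotypeMatrix as two-letter HapMap text (missing -> NN)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(HAPMAP_COLUMNS + tuple(gt.samples)) + "\n")
        for m, row in zip(gt.markers, gt.dosages):
            minor = m.minor if m.minor is not None else "N"
            major = m.major if m.major is not None else "N"
            alleles = f"{minor}/{major}" if m.minor is not None else major
            calls = []
            for d in row:
                if np.isnan(d):
                    calls.append("NN")
                elif d == 0:
                    calls.append(major + major)
                elif d == 1:
                    calls.append("".join(sorted((minor, major))))
                else:
                    calls.append(minor + minor)
            meta = [m.name, alleles, str(m.chrom), str(m.pos), "+",
                    "NA", "NA", "NA", "NA", "NA", "NA"]
            fh.write("\t".join(meta + calls) + "\n")
    return path


def write_association(assoc: AssociationTable, path: PathLike) -> Path:
    """Write an AssociationTable as TSV with TASSEL-style headers."""
    path = Path(path)
    df = assoc.table.rename(
        columns={"marker": "Marker", "chrom": "Locus", "pos": "Site", "p": "p"}
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def write_gtf(ann: AnnotationSet, path: PathLike) -> Path:
    """Write an AnnotationSet as GTF (exon/CDS/UTR rows only)."""
    path = Path(path)
    rows = []
    for tx in ann.transcripts.values():
        for kind, start, end in tx.features:
            rows.append((tx.chrom, start, end, kind, tx.strand,
                         tx.gene_id, tx.transcript_id))
    rows.sort(key=lambda r: (_chrom_key(r[0]), r[1], r[2], r[3]))
    with open(path, "w") as fh:
        for chrom, start, end, kind, strand, gid, tid in rows:
            attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            fh.write(
                f"{chrom}\tgwaslink\t{kind}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )
    return path
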