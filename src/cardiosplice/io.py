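"""Domain types and readers/writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open; GTF (1-based closed) is
converted at the reader boundary.  Sequence windows are always reported
5'->3' on the transcribed strand.  Interval overlaps (eCLIP peaks, protein
domains) are strand-blind by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("iPSC-CVPC", "adult_heart", "adult_arteria", "HF_pre", "HF_post")
HEALTHY_TISSUES = ("iPSC-CVPC", "adult_heart", "adult_arteria")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------

@dataclass
class SampleRecord:
    """One bulk RNA-seq sample with its technical covariates."""

    sample_id: str
    subject_id: str
    tissue: str
    sex: str
    total_reads: int
    pct_autosomal: float
    pct_mito: float

    def validate(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(
                f"unknown tissue label {self.tissue!r} for sample {self.sample_id!r}"
            )
        if self.sex not in ("F", "M"):
            raise ValueError(f"unknown sex {self.sex!r} for sample {self.sample_id!r}")
        if not (0.0 <= self.pct_autosomal <= 1.0 and 0.0 <= self.pct_mito <= 1.0):
            raise ValueError(f"read fractions outside [0,1] for {self.sample_id!r}")
        if self.pct_autosomal + self.pct_mito > 1.0 + 1e-9:
            raise ValueError(
                f"pct_autosomal + pct_mito > 1 for sample {self.sample_id!r}"
            )


SAMPLE_COLUMNS = [
    "sample_id", "subject_id", "tissue", "sex",
    "total_reads", "pct_autosomal", "pct_mito",
]


def read_sample_table(path) -> list[SampleRecord]:
    """Read a sample table TSV, validating each row.  Row order is preserved."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id: {sorted(set(dup))}")
    records = []
    for _, row in df.iterrows():
        rec = SampleRecord(
            sample_id=row["sample_id"], subject_id=row["subject_id"],
            tissue=row["tissue"], sex=row["sex"],
            total_reads=int(row["total_reads"]),
            pct_autosomal=float(row["pct_autosomal"]),
            pct_mito=float(row["pct_mito"]),
        )
        rec.validate()
        records.append(rec)
    return records


def write_sample_table(records: list[SampleRecord], path) -> None:
    pd.DataFrame([vars(r) for r in records])[SAMPLE_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def samples_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Dense feature x sample matrix: TPM, usage fractions, or normalized values.

    ``values`` is a pandas DataFrame indexed by feature_id with sample_id
    columns.  ``kind`` is one of {"tpm", "usage", "normalized"}.
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self):
        if self.kind not in ("tpm", "usage", "normalized"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = self.values.to_numpy()
        if self.kind == "tpm" and vals.size and vals.min() < 0:
            raise ValueError("TPM matrix contains negative values")
        if self.kind == "usage" and vals.size and (vals.min() < 0 or vals.max() > 1 + 1e-9):
            raise ValueError("usage matrix has values outside [0,1]")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "FeatureMatrix":
        return FeatureMatrix(self.values[list(sample_ids)], self.kind)

    def subset_features(self, feature_ids) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[list(feature_ids)], self.kind)

    def write_tsv(self, path) -> None:
        # repr round-trips doubles bit-exactly
        self.values.to_csv(path, sep="\t", index_label="feature_id",
                           float_format=lambda x: repr(float(x)))


def read_feature_matrix(path, kind: str) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id",
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    return FeatureMatrix(df, kind)


# ---------------------------------------------------------------------------
# transcript annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonRecord:
    exon_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str


@dataclass
class GeneRecord:
    gene_id: str
    gene_name: str
    strand: str
    transcript_ids: list[str] = field(default_factory=list)


@dataclass
class TranscriptAnnotation:
    """Gene -> transcript -> exon hierarchy with coordinate-shared exon ids.

    Exons with identical (chrom, start, end, strand) collapse to a single
    :class:`ExonRecord` shared by every transcript that contains them.
    Transcript exon lists are ordered 5'->3' in transcription orientation.
    """

    genes: dict[str, GeneRecord]
    transcripts: dict[str, list[str]]  # transcript_id -> ordered exon_ids
    exons: dict[str, ExonRecord]
    transcript_gene: dict[str, str]

    def gene_of(self, transcript_id: str) -> str:
        return self.transcript_gene[transcript_id]

    def isoforms_of(self, gene_id: str) -> list[str]:
        return self.genes[gene_id].transcript_ids

    def exon_ids_of_transcripts(self, transcript_ids) -> set[str]:
        out: set[str] = set()
        for t in transcript_ids:
            out.update(self.transcripts[t])
        return out


def _sort_transcript_exons(exon_ids, exons, strand):
    return sorted(exon_ids, key=lambda e: exons[e].start, reverse=(strand == "-"))


def _parse_gtf_attrs(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf_annotation(path) -> TranscriptAnnotation:
    """Parse a Gencode-dialect GTF into a :class:`TranscriptAnnotation`.

    GTF 1-based closed coordinates become 0-based half-open.  Exon lines must
    carry gene_id, transcript_id and exon_id attributes; exons sharing an id
    must share coordinates.
    """
    genes: dict[str, GeneRecord] = {}
    transcripts: dict[str, set[str]] = {}
    exons: dict[str, ExonRecord] = {}
    transcript_gene: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            chrom, _src, _feat, start1, end1, _score, strand, _frame, attr = fields[:9]
            attrs = _parse_gtf_attrs(attr)
            try:
                gid, tid, eid = attrs["gene_id"], attrs["transcript_id"], attrs["exon_id"]
            except KeyError as exc:
                raise ValueError(f"line {ln}: exon lacks attribute {exc}") from exc
            rec = ExonRecord(eid, chrom, int(start1) - 1, int(end1), strand)
            if eid in exons and exons[eid] != rec:
                raise ValueError(f"line {ln}: exon_id {eid!r} reused with different coordinates")
            exons[eid] = rec
            gene = genes.setdefault(
                gid, GeneRecord(gid, attrs.get("gene_name", gid), strand)
            )
            if gene.strand != strand:
                raise ValueError(f"line {ln}: gene {gid!r} mixes strands")
            if tid not in transcripts:
                transcripts[tid] = set()
                gene.transcript_ids.append(tid)
                transcript_gene[tid] = gid
            elif transcript_gene[tid] != gid:
                raise ValueError(f"line {ln}: transcript {tid!r} assigned to two genes")
            transcripts[tid].add(eid)
    ordered = {
        tid: _sort_transcript_exons(eids, exons, genes[transcript_gene[tid]].strand)
        for tid, eids in transcripts.items()
    }
    return TranscriptAnnotation(genes, ordered, exons, transcript_gene)


def write_gtf_annotation(ann: TranscriptAnnotation, path) -> None:
    with open(path, "w") as fh:
        for gid in ann.genes:
            gene = ann.genes[gid]
            for tid in gene.transcript_ids:
                for eid in ann.transcripts[tid]:
                    ex = ann.exons[eid]
                    attrs = (
                        f'gene_id "{gid}"; transcript_id "{tid}"; '
                        f'exon_id "{eid}"; gene_name "{gene.gene_name}";'
                    )
                    fh.write(
                        f"{ex.chrom}\tsim\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{ex.strand}\t.\t{attrs}\n"
                    )


def gene_body_intervals(ann: TranscriptAnnotation) -> dict[str, tuple[str, int, int]]:
    """Per gene, the genomic span [min exon start, max exon end)."""
    out = {}
    for gid, gene in ann.genes.items():
        eids = ann.exon_ids_of_transcripts(gene.transcript_ids)
        if not eids:
            warnings.warn(f"gene {gid!r} has no exons; excluded from gene bodies")
            continue
        recs = [ann.exons[e] for e in eids]
        out[gid] = (recs[0].chrom, min(r.start for r in recs), max(r.end for r in recs))
    return out


# ---------------------------------------------------------------------------
# eCLIP peaks
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    experiment_id: str
    rbp_name: str
    cell_line: str
    intervals: list[tuple[str, int, int]]


def read_bed_peaks(path, experiment_id=None, rbp_name=None, cell_line="NA") -> PeakSet:
    """Read a BED6 file of eCLIP peaks (0-based half-open, kept verbatim).

    ``rbp_name`` defaults to the BED name column of the first line, else the
    file stem.
    """
    import os
    stem = os.path.splitext(os.path.basename(str(path)))[0]
    intervals = []
    name_col = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}: line {ln}: start >= end")
            if name_col is None and len(fields) > 3:
                name_col = fields[3]
            intervals.append((chrom, start, end))
    return PeakSet(
        experiment_id=experiment_id or stem,
        rbp_name=rbp_name or name_col or stem,
        cell_line=cell_line,
        intervals=intervals,
    )


def write_bed_peaks(ps: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in ps.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{ps.rbp_name}\t0\t.\n")


# ---------------------------------------------------------------------------
# PWMs (MEME-minimal dialect)
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    motif_id: str
    rbp_name: str
    columns: np.ndarray  # L x 4 over (A, C, G, T)

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != 4:
            raise ValueError("PWM columns must be L x 4")
        if self.columns.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.columns.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")

    def __len__(self):
        return self.columns.shape[0]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.columns.argmax(axis=1))


def read_meme_pwms(path) -> list[PWM]:
    """Read motifs from a MEME-minimal motif file (A C G T column order)."""
    pwms = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1]
            rbp = parts[2] if len(parts) > 2 else motif_id
            i += 1
            rows = []
            while i < len(lines):
                s = lines[i].strip()
                if s.startswith("letter-probability"):
                    i += 1
                    continue
                toks = s.split()
                if len(toks) == 4:
                    try:
                        rows.append([float(t) for t in toks])
                        i += 1
                        continue
                    except ValueError:
                        pass
                break
            pwms.append(PWM(motif_id, rbp, np.array(rows)))
        else:
            i += 1
    return pwms


def write_meme_pwms(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id} {p.rbp_name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(p)}\n")
            for row in p.columns:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# gene sets (GMT) and protein domains
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    name: str
    collection: str
    members: set[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gmt(path, collection="") -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets.append(GeneSet(fields[0], collection or fields[1], set(fields[2:])))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.collection] + sorted(s.members)) + "\n")


@dataclass
class DomainRecord:
    domain_name: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"domain {self.domain_name!r}: start >= end")


def read_domains(path) -> list[DomainRecord]:
    """BED-like domain table: chrom, start, end, name[, strand]."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            strand = f[4] if len(f) > 4 else "."
            out.append(DomainRecord(f[3] if len(f) > 3 else ".", f[0], int(f[1]), int(f[2]), strand))
    return out


def write_domains(domains: list[DomainRecord], path) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.domain_name}\t{d.strand}\n")


# ---------------------------------------------------------------------------
# genome access
# ---------------------------------------------------------------------------

class Genome:
    """Genome sequence access with strand-aware window extraction.

    Wraps either an in-memory dict {chrom: sequence} or a pyfaidx.Fasta.
    """

    def __init__(self, source):
        self._source = source

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from pyfaidx import Fasta
        return cls(Fasta(str(path), sequence_always_upper=True))

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "Genome":
        return cls({k: v.upper() for k, v in seqs.items()})

    def __contains__(self, chrom):
        return chrom in self._source

    def chrom_length(self, chrom: str) -> int:
        return len(self._source[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._source:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self._source[chrom][start:end]
        return str(seq).upper()

    def write_fasta(self, path, width=80) -> None:
        if not isinstance(self._source, dict):
            raise TypeError("only in-memory genomes can be written")
        with open(path, "w") as fh:
            for chrom, seq in self._source.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def extract_window(genome: Genome, chrom: str, anchor: int, length: int,
                   side: str, strand: str) -> tuple[str, bool]:
    """Extract a sequence window flanking ``anchor`` (a 0-based boundary).

    ``side`` is relative to transcription orientation: "up" means the window
    ends at the anchor (5' of it on the transcribed strand), "down" means it
    starts there.  Returns (sequence 5'->3' on the transcribed strand,
    truncated_flag); windows crossing chromosome bounds are truncated with a
    warning.
    """
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if side not in ("up", "down"):
        raise ValueError("side must be 'up' or 'down'")
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    # genomic orientation of the window
    genomic_before = (side == "up") == (strand == "+")
    if genomic_before:
        start, end = anchor - length, anchor
    else:
        start, end = anchor, anchor + length
    clen = genome.chrom_length(chrom)
    truncated = start < 0 or end > clen
    if truncated:
        warnings.warn(f"window [{start},{end}) truncated to chromosome {chrom} bounds")
    seq = genome.fetch(chrom, max(start, 0), min(end, clen))
    if strand == "-":
        seq = revcomp(seq)
    return seq, truncated
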