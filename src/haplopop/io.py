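"""Readers and writers for the standard formats used by the pipeline.

Internal coordinate convention: everything is 0-based, half-open.  VCF and
GFF3 are 1-based on disk; the conversion happens here and only here.  The
genotype matrix is haploid: one allele index per sample per site, with
``MISSING`` (-1) marking calls that are absent or have been filtered out.
Heterozygous diploid genotypes in the input VCF are loaded but flagged, so the
QC stage can mask them (a heterozygous call in a haploid organism is treated
as a genotyping error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

MISSING = -1

#: feature types the annotation reader recognises; anything else is kept with
#: the generic tag "other"
KNOWN_FEATURE_TYPES = frozenset(
    {
        "gene",
        "CDS",
        "five_prime_UTR",
        "three_prime_UTR",
        "intron",
        "ncRNA",
        "tRNA",
        "rRNA",
        "snoRNA",
        "pseudogene",
        "repeat",
        "centromere",
        "telomere",
        "transposable_element",
    }
)


@dataclass
class ReferenceGenome:
    """An ordered set of chromosomes with uppercase sequences over {A,C,G,T,N}."""

    names: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            seen: set[str] = set()
            for n in self.names:
                if n in seen:
                    raise ValueError(f"duplicate chromosome name: {n!r}")
                seen.add(n)
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in zip(self.names, self.sequences)}

    def sequence(self, chrom: str) -> str:
        return self.sequences[self.names.index(chrom)]


@dataclass
class Feature:
    """A single annotation feature, 0-based half-open."""

    type: str
    chrom: str
    start: int
    end: int
    strand: str
    id: str | None = None
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature {self.id or self.type} has start {self.start} >= end {self.end}"
            )


@dataclass
class AnnotationSet:
    features: list[Feature] = field(default_factory=list)

    def of_type(self, *types: str) -> list[Feature]:
        want = set(types)
        return [f for f in self.features if f.type in want]

    def children_of(self, parent_id: str) -> list[Feature]:
        return [f for f in self.features if f.parent == parent_id]


@dataclass
class MarkerTable:
    """Genetic-map markers: physical (bp) and genetic (cM) marker positions."""

    table: pd.DataFrame  # columns: chrom, bp, cM

    def __post_init__(self) -> None:
        required = {"chrom", "bp", "cM"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"marker table must have columns {sorted(required)}")
        if (self.table["cM"] < 0).any():
            raise ValueError("negative cM position in marker table")

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        sub = self.table[self.table["chrom"] == chrom]
        return sub.sort_values("bp").reset_index(drop=True)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))


@dataclass
class GenotypeMatrix:
    """Haploid genotype calls at ordered sites across one or more chromosomes.

    ``calls[i, s]`` is the allele index of sample ``i`` at site ``s`` (0 = ref,
    1.. = alternates) or ``MISSING``.  ``het[i, s]`` flags calls loaded from
    heterozygous diploid genotypes; they carry the first allele but are
    expected to be masked downstream.
    """

    samples: list[str]
    chrom: np.ndarray  # (S,) str
    pos: np.ndarray  # (S,) int64, 0-based
    ref: np.ndarray  # (S,) str
    alts: list[tuple[str, ...]]
    calls: np.ndarray  # (n, S) int16
    qual: np.ndarray  # (S,) float64
    depth: np.ndarray  # (n, S) int32
    het: np.ndarray  # (n, S) bool

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ValueError("need at least 2 samples")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return self.pos.shape[0]

    @property
    def chrom_names(self) -> list[str]:
        return list(dict.fromkeys(self.chrom.tolist()))

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=self.samples,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alts=[self.alts[i] for i in np.atleast_1d(idx)],
            calls=self.calls[:, idx],
            qual=self.qual[idx],
            depth=self.depth[:, idx],
            het=self.het[:, idx],
        )


# ---------------------------------------------------------------------------
# readers


def read_reference(path: str | Path) -> ReferenceGenome:
    """Read a (multi-)FASTA reference; sequences are uppercased."""
    names: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in names:
            raise ValueError(f"duplicate chromosome name: {rec.id!r}")
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not names:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceGenome(names, seqs)


def read_variants(path: str | Path, reference: ReferenceGenome | None = None) -> GenotypeMatrix:
    """Read a VCF of haploid (or diploid-homozygous) genotype calls.

    POS is converted to 0-based.  Diploid homozygous genotypes collapse to a
    single allele; heterozygous genotypes are loaded with the ``het`` flag set.
    Records are sorted by position within each chromosome.
    """
    lengths = reference.lengths if reference is not None else None
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if len(samples) < 2:
        raise ValueError("VCF must contain at least 2 samples")
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    quals: list[float] = []
    calls_rows: list[list[int]] = []
    depth_rows: list[list[int]] = []
    het_rows: list[list[bool]] = []
    for rec in vf:
        pos0 = rec.pos - 1
        if lengths is not None:
            if rec.chrom not in lengths:
                raise ValueError(f"VCF chromosome {rec.chrom!r} not in reference")
            if pos0 >= lengths[rec.chrom]:
                raise ValueError(
                    f"VCF position {rec.pos} beyond length of {rec.chrom} ({lengths[rec.chrom]})"
                )
        rec_calls: list[int] = []
        rec_depth: list[int] = []
        rec_het: list[bool] = []
        for s in samples:
            sample = rec.samples[s]
            gt = sample.get("GT")
            if gt is None or all(a is None for a in gt):
                allele, is_het = MISSING, False
            else:
                alleles = [a for a in gt if a is not None]
                allele = alleles[0]
                is_het = len(set(alleles)) > 1
            dp = sample.get("DP")
            rec_calls.append(int(allele))
            rec_depth.append(int(dp) if dp is not None else 0)
            rec_het.append(is_het)
        chroms.append(rec.chrom)
        poss.append(pos0)
        refs.append(rec.ref)
        alts.append(tuple(a for a in (rec.alts or ()) if a != "."))
        quals.append(float(rec.qual) if rec.qual is not None else np.nan)
        calls_rows.append(rec_calls)
        depth_rows.append(rec_depth)
        het_rows.append(rec_het)
    vf.close()
    if not poss:
        raise ValueError(f"no variant records found in {path}")

    chrom_arr = np.array(chroms, dtype=object)
    pos_arr = np.array(poss, dtype=np.int64)
    # stable sort by (chromosome order of first appearance, position)
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(chroms))}
    order = np.lexsort((pos_arr, np.array([chrom_order[c] for c in chroms])))
    return GenotypeMatrix(
        samples=samples,
        chrom=chrom_arr[order],
        pos=pos_arr[order],
        ref=np.array(refs, dtype=object)[order],
        alts=[alts[i] for i in order],
        calls=np.array(calls_rows, dtype=np.int16).T[:, order],
        qual=np.array(quals, dtype=np.float64)[order],
        depth=np.array(depth_rows, dtype=np.int32).T[:, order],
        het=np.array(het_rows, dtype=bool).T[:, order],
    )


def read_annotation(path: str | Path) -> AnnotationSet:
    """Read a GFF3 file into 0-based half-open features."""
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            try:
                f = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # pragma: no cover - gffutils detail
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line: {exc}") from exc
            if f.end < f.start:
                raise ValueError(f"{path}:{lineno}: end < start")
            ftype = f.featuretype if f.featuretype in KNOWN_FEATURE_TYPES else "other"
            fid = f.attributes.get("ID", [None])[0]
            parent = f.attributes.get("Parent", [None])[0]
            features.append(
                Feature(
                    type=ftype,
                    chrom=f.seqid,
                    start=f.start - 1,
                    end=f.end,
                    strand=f.strand if f.strand in "+-" else "+",
                    id=fid,
                    parent=parent,
                )
            )
    return AnnotationSet(features)


def read_markers(path: str | Path) -> MarkerTable:
    """Read a TSV genetic-map marker table with header ``chrom\\tbp\\tcM``."""
    df = pd.read_csv(path, sep="\t")
    return MarkerTable(df)


def read_callable_bed(path: str | Path) -> dict[str, np.ndarray]:
    """Read a BED of callable intervals into {chrom: (k, 2) int array}."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(start), int(end)))
    return {c: np.array(sorted(iv), dtype=np.int64).reshape(-1, 2) for c, iv in out.items()}


# ---------------------------------------------------------------------------
# writers — deterministic plain text


def write_fasta(reference: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(reference.names, reference.sequences):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(intervals: dict[str, np.ndarray], path: str | Path) -> None:
    """Write {chrom: (k, 2) interval array} as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in intervals:
            for row in np.asarray(intervals[chrom]).reshape(-1, 2):
                fh.write(f"{chrom}\t{row[0]}\t{row[1]}\n")


def write_vcf(matrix: GenotypeMatrix, path: str | Path, contig_lengths=None) -> None:
    """Write a GenotypeMatrix as a haploid VCF (positions back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplopop\n")
        if contig_lengths:
            for c, l in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for s in range(matrix.n_sites):
            alt = ",".join(matrix.alts[s]) if matrix.alts[s] else "."
            q = matrix.qual[s]
            qual = "." if np.isnan(q) else f"{q:g}"
            cols = [
                str(matrix.chrom[s]),
                str(matrix.pos[s] + 1),
                ".",
                str(matrix.ref[s]),
                alt,
                qual,
                "PASS",
                ".",
                "GT:DP",
            ]
            for i in range(matrix.n_samples):
                a = matrix.calls[i, s]
                gt = "." if a == MISSING else str(int(a))
                cols.append(f"{gt}:{matrix.depth[i, s]}")
            fh.write("\t".join(cols) + "\n")


def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in annotation.features:
            attrs = []
            if f.id:
                attrs.append(f"ID={f.id}")
            if f.parent:
                attrs.append(f"Parent={f.parent}")
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        "haplopop",
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs) or ".",
                    ]
                )
                + "\n"
            )


def write_markers(markers: MarkerTable, path: str | Path) -> None:
    markers.table.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def write_window_stats(df: pd.DataFrame, path: str | Path) -> None:
    """Write window statistics as BED-compatible TSV (chrom/start/end first)."""
    lead = [c for c in ("chrom", "start", "end") if c in df.columns]
    rest = [c for c in df.columns if c not in lead]
    df[lead + rest].to_csv(
        path, sep="\t", index=False, float_format="%.10g", lineterminator="\n"
    )


def write_newick(newick: str, path: str | Path) -> None:
    if not newick.endswith(";"):
        newick += ";"
    with open(path, "w") as fh:
        fh.write(newick + "\n")


def write_tables(results: dict, out_dir: str | Path) -> list[Path]:
    """Write a dict of named stage outputs to ``out_dir``.

    DataFrames become TSV, newick strings become ``.nwk``, dicts become
    key-value TSV.  Output is byte-stable given identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}.tsv"
            write_window_stats(obj, p)
        elif isinstance(obj, str) and (obj.endswith(";") or obj.startswith("(")):
            p = out_dir / f"{name}.nwk"
            write_newick(obj, p)
        elif isinstance(obj, dict):
            p = out_dir / f"{name}.tsv"
            with open(p, "w") as fh:
                for k, v in obj.items():
                    fh.write(f"{k}\t{v:.10g}\n" if isinstance(v, float) else f"{k}\t{v}\n")
        else:
            raise TypeError(f"cannot serialise result {name!r} of type {type(obj)}")
        written.append(p)
    return written
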