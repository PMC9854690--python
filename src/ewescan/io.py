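"""Readers/writers for the text formats the scan touches.

Genotypes travel as PLINK-style PED/MAP text (one PED row per individual:
six pedigree columns then two allele letters per marker; "0 0" = missing).
Gene annotations come in as GFF3 (gene-typed features only, via gffutils)
or BED (half-open 0-based, converted to 1-based inclusive at this boundary).
All internal coordinates are 1-based inclusive.

Result-table writers (TSV/BED) stamp a ``#`` header comment with the package
version and, when given, the seed/config hash; PED/MAP files are left
comment-free because the PLINK dialect has no comment syntax.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__

MISSING = -1  # sentinel genotype code (alt-allele count otherwise 0/1/2)

#: column order of a MarkerMap frame
MAP_COLUMNS = ["chrom", "snp", "cm", "bp", "allele_a", "allele_b"]


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype codes (alt-allele counts).

    ``codes`` is int8 with entries in {0, 1, 2, MISSING}; rows follow
    ``individual_ids`` and columns follow ``marker_ids``.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.marker_ids)} markers"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0/1/2 or the missing sentinel")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset_markers(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            marker_ids=[self.marker_ids[j] for j in keep],
            codes=self.codes[:, keep],
        )


@dataclass
class GeneRecord:
    """One gene: 1-based inclusive coordinates on a chromosome."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"gene {self.name}: invalid interval [{self.start}, {self.end}]")


def validate_marker_map(marker_map: pd.DataFrame) -> pd.DataFrame:
    """Check MarkerMap invariants; returns the frame unchanged.

    Unique marker ids, bp >= 1, positions strictly increasing within each
    chromosome (chromosome blocks in file order).
    """
    missing_cols = [c for c in MAP_COLUMNS if c not in marker_map.columns]
    if missing_cols:
        raise FormatError(f"marker map missing columns: {missing_cols}")
    if marker_map["snp"].duplicated().any():
        dups = marker_map.loc[marker_map["snp"].duplicated(), "snp"].tolist()[:5]
        raise FormatError(f"duplicate marker ids: {dups}")
    if (marker_map["bp"] < 1).any():
        raise FormatError("bp positions must be >= 1")
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        if not grp["bp"].is_monotonic_increasing or grp["bp"].duplicated().any():
            raise FormatError(f"bp positions not strictly increasing on chromosome {chrom}")
    return marker_map


def _result_header(seed: int | None = None, extra: str | None = None) -> str:
    parts = [f"ewescan v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if extra:
        parts.append(extra)
    return "# " + " ".join(parts) + "\n"


def write_tsv(frame: pd.DataFrame, path: str | os.PathLike, *, seed: int | None = None,
              extra: str | None = None) -> None:
    """Write a result table as TSV with a version/seed header comment."""
    with open(path, "w") as fh:
        fh.write(_result_header(seed, extra))
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------

def read_map(map_path: str | os.PathLike) -> pd.DataFrame:
    """Read a PLINK MAP file (chrom, snp id, cM, bp) into a MarkerMap frame.

    Allele columns are filled in later by :func:`read_ped_map` (MAP carries
    no allele dictionary).
    """
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tok = line.split()
            if len(tok) != 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 columns, got {len(tok)}")
            rows.append((tok[0], tok[1], float(tok[2]), int(tok[3])))
    frame = pd.DataFrame(rows, columns=["chrom", "snp", "cm", "bp"])
    frame["allele_a"] = ""
    frame["allele_b"] = ""
    return frame


def read_ped_map(ped_path: str | os.PathLike, map_path: str | os.PathLike,
                 ref_alleles: dict[str, str] | None = None
                 ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read PED+MAP into a GenotypeMatrix and MarkerMap.

    Allele pairs collapse to alt-allele counts against a per-marker allele
    dictionary: the first-seen non-missing allele becomes the reference
    (code 0 when homozygous) by default; pass ``ref_alleles`` (marker id ->
    allele letter) to pin the reference explicitly, e.g. for a lossless
    round trip of files this package wrote.  "0 0" becomes the missing
    sentinel.  All downstream statistics are invariant to the default's
    arbitrary labeling.
    """
    marker_map = read_map(map_path)
    n_markers = len(marker_map)
    individual_ids: list[str] = []
    rows: list[np.ndarray] = []
    # per-marker allele dictionary: [ref, alt] discovered in file order,
    # optionally pre-seeded with the pinned reference
    alleles: list[list[str]] = [[] for _ in range(n_markers)]
    if ref_alleles:
        for j, snp in enumerate(marker_map["snp"]):
            if snp in ref_alleles:
                alleles[j].append(ref_alleles[snp])

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tok = line.split()
            if len(tok) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} tokens "
                    f"for {n_markers} markers, got {len(tok)}"
                )
            individual_ids.append(tok[1])
            codes = np.empty(n_markers, dtype=np.int8)
            geno = tok[6:]
            for j in range(n_markers):
                a1, a2 = geno[2 * j], geno[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    if a1 != a2:
                        raise FormatError(
                            f"{ped_path}:{lineno}: half-missing genotype at marker "
                            f"{marker_map['snp'].iat[j]}"
                        )
                    codes[j] = MISSING
                    continue
                seen = alleles[j]
                code = 0
                for allele in (a1, a2):
                    if allele not in seen:
                        if len(seen) == 2:
                            raise FormatError(
                                f"marker {marker_map['snp'].iat[j]} is not biallelic: "
                                f"alleles {seen + [allele]}"
                            )
                        seen.append(allele)
                    code += seen.index(allele)
                codes[j] = code
            rows.append(codes)

    marker_map["allele_a"] = [a[0] if a else "A" for a in alleles]
    marker_map["allele_b"] = [a[1] if len(a) > 1 else "B" for a in alleles]
    matrix = GenotypeMatrix(
        individual_ids=individual_ids,
        marker_ids=marker_map["snp"].tolist(),
        codes=np.vstack(rows) if rows else np.empty((0, n_markers), dtype=np.int8),
    )
    return matrix, validate_marker_map(marker_map)


def write_ped_map(matrix: GenotypeMatrix, marker_map: pd.DataFrame,
                  ped_path: str | os.PathLike, map_path: str | os.PathLike) -> None:
    """Write PED/MAP text; code 0 -> "a a", 1 -> "a b", 2 -> "b b", missing -> "0 0"."""
    validate_marker_map(marker_map)
    if list(matrix.marker_ids) != marker_map["snp"].tolist():
        raise ValueError("matrix marker ids do not match the marker map")
    with open(map_path, "w") as fh:
        for row in marker_map.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp}\t{row.cm:g}\t{row.bp}\n")
    a = marker_map["allele_a"].to_numpy(dtype=object)
    b = marker_map["allele_b"].to_numpy(dtype=object)
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(matrix.individual_ids):
            fields = [ind.split("_")[0] if "_" in ind else "FAM", ind, "0", "0", "0", "-9"]
            codes = matrix.codes[i]
            for j, c in enumerate(codes):
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [a[j], a[j]]
                elif c == 1:
                    fields += [a[j], b[j]]
                else:
                    fields += [b[j], b[j]]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | os.PathLike, fmt: str = "auto") -> list[GeneRecord]:
    """Read genes from GFF3 or BED into 1-based inclusive GeneRecords.

    ``fmt`` in {"gff3", "bed", "auto"} ("auto" keys on the file extension).
    """
    fmt = fmt.lower()
    if fmt == "auto":
        ext = os.path.splitext(str(path))[1].lower()
        if ext in (".gff", ".gff3"):
            fmt = "gff3"
        elif ext == ".bed":
            fmt = "bed"
        else:
            raise FormatError(f"cannot infer annotation format from extension {ext!r}")
    if fmt == "gff3":
        return _read_gff3(path)
    if fmt == "bed":
        return _read_bed(path)
    raise FormatError(f"unknown annotation format {fmt!r} (expected gff3 or bed)")


def _read_gff3(path: str | os.PathLike) -> list[GeneRecord]:
    import gffutils

    if os.path.getsize(path) == 0 or not any(
        line.strip() and not line.startswith("#") for line in open(path)
    ):
        return []
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        strand = feat.strand if feat.strand in ("+", "-") else None
        genes.append(GeneRecord(name=name, chrom=feat.seqid, start=feat.start,
                                end=feat.end, strand=strand))
    return genes


def _read_bed(path: str | os.PathLike) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            tok = line.split()
            if len(tok) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start0, end = tok[0], int(tok[1]), int(tok[2])
            name = tok[3] if len(tok) > 3 else f"feature{lineno}"
            strand = tok[5] if len(tok) > 5 and tok[5] in ("+", "-") else None
            # BED half-open 0-based -> 1-based inclusive
            genes.append(GeneRecord(name=name, chrom=chrom, start=start0 + 1,
                                    end=end, strand=strand))
    return genes


def write_gff3(genes: Iterable[GeneRecord], path: str | os.PathLike,
               *, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(_result_header(seed))
        for g in genes:
            strand = g.strand or "."
            fh.write(f"{g.chrom}\tewescan\tgene\t{g.start}\t{g.end}\t.\t{strand}\t.\t"
                     f"ID={g.name};Name={g.name}\n")


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | os.PathLike,
              *, seed: int | None = None) -> None:
    """Write 1-based inclusive (chrom, start, end, name) tuples as BED."""
    with open(path, "w") as fh:
        fh.write(_result_header(seed))
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
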