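"""Readers, writers and in-memory containers for the formats the pipeline touches.

The central containers are :class:`MatrixBundle` (cells x features with named
2-D layers), :class:`VariantRecord` tables read from VCF, and
:class:`AmpliconRecord` tables read from BED.  All genomic intervals are held
0-based half-open internally; VCF positions are converted on ingest
(``pos - 1``) so that a VCF position ``p`` lies inside amplicon ``[s, e)``
iff ``s < p <= e`` in 1-based terms.

On-disk matrix dialect: tab-delimited, one file per layer, first row holds
feature ids, first column holds cell ids, missing genotypes written as
``NA``.  The dialect is diff-able and language-neutral; an HDF5 mirror is
deliberately not required.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Genotype codes: 0 = reference, 1 = heterozygous, 2 = homozygous alternate.
#: The missing sentinel is a distinct code, never conflated with 0 --
#: downstream filters treat ungenotyped entries specially.
MISSING = 3

#: Layers that make up a genotype bundle and an amplicon-count bundle.
GENOTYPE_LAYERS = ("NGT", "DP", "GQ", "AF")
COUNT_LAYERS = ("COUNT",)

_INT_LAYERS = {"NGT", "DP", "GQ", "COUNT"}


class FormatError(ValueError):
    """Raised when an on-disk file violates the dialect or format contract."""


@dataclass
class VariantRecord:
    """One ALT allele at one genomic site, with optional bulk annotations."""

    chrom: str
    pos: int  # 1-based, as printed in VCF
    ref: str
    alt: str
    gene: str = ""
    variant_class: str = "other"
    bulk_vaf: float = float("nan")
    depth: int = 0
    annotations: dict = field(default_factory=dict)

    @property
    def pos0(self) -> int:
        """0-based position (internal coordinate convention)."""
        return self.pos - 1

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")


@dataclass
class AmpliconRecord:
    """A PCR-targeted interval: the unit of read-depth measurement."""

    amplicon_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    gc_fraction: float = float("nan")
    primer_gc: float = float("nan")
    primer_len: int = 0
    overlaps: list = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end} "
                f"({self.amplicon_id})"
            )

    def contains_vcf_pos(self, chrom: str, pos: int) -> bool:
        """True iff 1-based VCF position ``pos`` falls inside this amplicon."""
        return chrom == self.chrom and self.start < pos <= self.end


@dataclass
class MatrixBundle:
    """Cells x features matrix with named, shape-aligned 2-D layers.

    Genotype bundles carry NGT/DP/GQ/AF layers; amplicon-count bundles carry a
    single COUNT layer.  ``feature_ids`` are variant ids or amplicon ids
    depending on the bundle kind.
    """

    cell_ids: list
    feature_ids: list
    layers: dict

    def __post_init__(self):
        self.cell_ids = list(self.cell_ids)
        self.feature_ids = list(self.feature_ids)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell_ids in bundle")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature_ids in bundle")
        shape = (len(self.cell_ids), len(self.feature_ids))
        for name, arr in self.layers.items():
            arr = np.asarray(arr)
            if arr.shape != shape:
                raise FormatError(
                    f"layer {name!r} has shape {arr.shape}, expected {shape}"
                )
            self.layers[name] = arr
        self.validate()

    @property
    def shape(self) -> tuple:
        return (len(self.cell_ids), len(self.feature_ids))

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def validate(self):
        if "NGT" in self.layers:
            ngt = self.layers["NGT"]
            bad = ~np.isin(ngt, (0, 1, 2, MISSING))
            if bad.any():
                raise FormatError(f"NGT contains codes outside {{0,1,2,{MISSING}}}")
        if "DP" in self.layers and (self.layers["DP"] < 0).any():
            raise FormatError("DP contains negative depths")
        if "COUNT" in self.layers and (self.layers["COUNT"] < 0).any():
            raise FormatError("COUNT contains negative depths")
        if "AF" in self.layers:
            af = self.layers["AF"]
            finite = np.isfinite(af)
            if ((af[finite] < 0) | (af[finite] > 1)).any():
                raise FormatError("AF outside [0, 1]")

    def layer_frame(self, name: str) -> pd.DataFrame:
        return pd.DataFrame(
            self.layers[name], index=self.cell_ids, columns=self.feature_ids
        )

    def subset(self, cells=None, features=None) -> "MatrixBundle":
        """New bundle restricted to the given cell/feature ids (order kept)."""
        cells = list(cells) if cells is not None else self.cell_ids
        features = list(features) if features is not None else self.feature_ids
        ci = pd.Index(self.cell_ids).get_indexer(cells)
        fi = pd.Index(self.feature_ids).get_indexer(features)
        if (ci < 0).any() or (fi < 0).any():
            raise KeyError("subset requested unknown cell or feature ids")
        layers = {k: np.asarray(v)[np.ix_(ci, fi)] for k, v in self.layers.items()}
        return MatrixBundle(cells, features, layers)

    def equals(self, other: "MatrixBundle") -> bool:
        if self.cell_ids != other.cell_ids or self.feature_ids != other.feature_ids:
            return False
        if set(self.layers) != set(other.layers):
            return False
        return all(
            np.array_equal(self.layers[k], other.layers[k], equal_nan=True)
            for k in self.layers
        )


# ---------------------------------------------------------------------------
# matrix dialect
# ---------------------------------------------------------------------------

def write_matrix_bundle(prefix: str, bundle: MatrixBundle) -> list:
    """Write one ``<prefix>.<LAYER>.tsv`` file per layer; returns the paths.

    NGT missing codes are written as ``NA``; NaN in float layers likewise.
    """
    bundle.validate()
    paths = []
    for name, arr in bundle.layers.items():
        frame = bundle.layer_frame(name)
        if name == "NGT":
            frame = frame.astype(object).mask(frame == MISSING, "NA")
        path = f"{prefix}.{name}.tsv"
        frame.to_csv(path, sep="\t", index_label="cell_id", na_rep="NA")
        paths.append(path)
    return paths


def read_matrix_bundle(prefix: str, layer_names=None) -> MatrixBundle:
    """Read a bundle written by :func:`write_matrix_bundle`.

    ``layer_names`` defaults to whatever ``<prefix>.*.tsv`` files exist.
    """
    if layer_names is None:
        base = os.path.basename(prefix) + "."
        directory = os.path.dirname(prefix) or "."
        layer_names = sorted(
            f[len(base):-4]
            for f in os.listdir(directory)
            if f.startswith(base) and f.endswith(".tsv")
        )
    if not layer_names:
        raise FormatError(f"no layer files found for prefix {prefix!r}")
    unknown = set(layer_names) - set(GENOTYPE_LAYERS) - set(COUNT_LAYERS)
    if unknown:
        raise FormatError(f"unknown layer names: {sorted(unknown)}")
    layers, cell_ids, feature_ids = {}, None, None
    for name in layer_names:
        frame = pd.read_csv(
            f"{prefix}.{name}.tsv", sep="\t", index_col=0,
            keep_default_na=False, na_values=["NA"],
        )
        if frame.index.has_duplicates:
            raise FormatError(f"duplicate cell_ids in layer {name}")
        if cell_ids is None:
            cell_ids = list(frame.index)
            feature_ids = list(frame.columns)
        elif list(frame.index) != cell_ids or list(frame.columns) != feature_ids:
            raise FormatError(f"layer {name} labels disagree with other layers")
        arr = frame.to_numpy()
        if name == "NGT":
            arr = np.where(pd.isna(arr), MISSING, arr).astype(int)
        elif name in _INT_LAYERS:
            arr = arr.astype(int)
        else:
            arr = arr.astype(float)
        layers[name] = arr
    return MatrixBundle(cell_ids, feature_ids, layers)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

#: Default INFO keys carrying bulk annotations; the true keys used upstream
#: vary by annotation tool, so they are configurable at the call site.
DEFAULT_INFO_KEYS = {
    "bulk_vaf": "AF",
    "gene": "GENE",
    "variant_class": "VC",
    "polyphen": "POLYPHEN",
    "sift": "SIFT",
    "cadd": "CADD",
    "supporting_reads": "SR",
}

_ANNOTATION_NAMES = ("polyphen", "sift", "cadd")


def read_variant_table(path: str, info_keys: dict | None = None) -> pd.DataFrame:
    """Read a VCF into a variant table, one row per ALT allele.

    Multi-allelic sites are split; ``bulk_vaf`` and annotation scores are
    pulled from INFO under the (configurable) key map.  Missing INFO keys are
    treated as absent annotations, not errors.
    """
    from cyvcf2 import VCF

    keys = dict(DEFAULT_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)
    records = []
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot parse VCF {path!r}: {exc}") from exc
    for var in vcf:
        alts = var.ALT or []
        n_alt = len(alts)
        for i, alt in enumerate(alts):

            def _info(name, default=None):
                value = var.INFO.get(keys[name])
                if value is None:
                    return default
                if isinstance(value, tuple):
                    value = value[i] if i < len(value) and n_alt > 1 else value[0]
                return value

            annotations = {}
            for score in _ANNOTATION_NAMES:
                value = _info(score)
                if value is not None:
                    annotations[score] = float(value)
            rec = VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=alt,
                gene=str(_info("gene", "")),
                variant_class=str(_info("variant_class", "other")),
                bulk_vaf=float(_info("bulk_vaf", float("nan"))),
                depth=0 if var.INFO.get("DP") is None else int(var.INFO.get("DP")),
                annotations=annotations,
            )
            row = {
                "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
                "gene": rec.gene, "variant_class": rec.variant_class,
                "bulk_vaf": rec.bulk_vaf, "depth": rec.depth,
            }
            sr = _info("supporting_reads")
            if sr is not None:
                row["supporting_reads"] = int(sr)
            for score in _ANNOTATION_NAMES:
                row[score] = annotations.get(score, float("nan"))
            records.append(row)
    table = pd.DataFrame(
        records,
        columns=["chrom", "pos", "ref", "alt", "gene", "variant_class",
                 "bulk_vaf", "depth", "supporting_reads", *_ANNOTATION_NAMES],
    )
    if len(table) and table.duplicated(["chrom", "pos", "ref", "alt"]).any():
        raise FormatError(f"duplicate (chrom,pos,ref,alt) records in {path!r}")
    return table


def write_variant_table(path: str, table: pd.DataFrame,
                        info_keys: dict | None = None) -> str:
    """Write a variant table back to a minimal site-only VCF 4.2 file."""
    keys = dict(DEFAULT_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)
    float_fields = ["bulk_vaf", *_ANNOTATION_NAMES]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in float_fields:
            fh.write(
                f'##INFO=<ID={keys[name]},Number=1,Type=Float,Description="{name}">\n'
            )
        for name in ("gene", "variant_class"):
            fh.write(
                f'##INFO=<ID={keys[name]},Number=1,Type=String,Description="{name}">\n'
            )
        fh.write('##INFO=<ID=SR,Number=1,Type=Integer,Description="supporting reads">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in table.iterrows():
            info = []
            for name in float_fields:
                value = row.get(name, float("nan"))
                if pd.notna(value):
                    info.append(f"{keys[name]}={float(value):g}")
            for name in ("gene", "variant_class"):
                value = row.get(name, "")
                if value:
                    info.append(f"{keys[name]}={value}")
            if pd.notna(row.get("supporting_reads", None)):
                info.append(f"SR={int(row['supporting_reads'])}")
            if row.get("depth", 0):
                info.append(f"DP={int(row['depth'])}")
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t{';'.join(info) or '.'}\n"
            )
    return path


# ---------------------------------------------------------------------------
# BED panels
# ---------------------------------------------------------------------------

def read_panel_bed(path: str, genome: str | None = None) -> list:
    """Read amplicon intervals from a BED file (3+ columns, optional name).

    If ``genome`` (a FASTA path) is supplied, per-amplicon GC fraction is
    computed from the sequence; otherwise it is left NaN.  Pairwise overlaps
    among the records are filled in.
    """
    fasta = None
    if genome is not None:
        from pyfaidx import Fasta

        fasta = Fasta(genome)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            name = fields[3] if len(fields) > 3 else f"amp_{lineno}"
            gc = float("nan")
            if fasta is not None:
                seq = str(fasta[chrom][start:end])
                from .panel import gc_fraction

                gc = gc_fraction(seq)
            records.append(AmpliconRecord(name, chrom, start, end, gc_fraction=gc))
    _fill_overlaps(records)
    return records


def _fill_overlaps(records: list) -> None:
    """Populate ``overlaps`` on each record by pairwise interval intersection."""
    for rec in records:
        rec.overlaps = []
    by_chrom: dict = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for recs in by_chrom.values():
        recs = sorted(recs, key=lambda r: r.start)
        for i, a in enumerate(recs):
            for b in recs[i + 1:]:
                if b.start >= a.end:
                    break
                a.overlaps.append(b.amplicon_id)
                b.overlaps.append(a.amplicon_id)


def write_panel_bed(path: str, records: list) -> str:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.amplicon_id}\n")
    return path
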