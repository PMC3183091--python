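"""Domain types and file formats shared by every pipeline stage.

The pipeline operates on a probe x sample intensity matrix from sorted
inner-ear cell populations (four cell types x two organs x replicates),
together with gene sets (GMT), gene/locus intervals (BED, 0-based
half-open), promoter sequences (FASTA) and a protein-protein interaction
edge list (TSV).  Everything here is deliberately strict: malformed input
raises :class:`FormatError` with the offending location rather than being
silently truncated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx

CELL_TYPES = ("sensory", "neuronal", "endothelial", "mesenchymal")
ORGANS = ("cochlea", "vestibule")
GENOTYPES = ("wt", "Tw_het", "Tw_hom")
COMPARTMENTS = ("CD326pos", "CD326neg")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# sample metadata and expression container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleDescriptor:
    """Metadata for one array: which sorted population it profiles."""

    sample_id: str
    cell_type: str
    organ: str
    replicate: int
    genotype: str | None = None
    compartment: str | None = None

    def __post_init__(self):
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def condition(self) -> tuple[str, str]:
        return (self.cell_type, self.organ)

    def is_wildtype(self) -> bool:
        return self.genotype in (None, "wt")


@dataclass
class ExpressionMatrix:
    """Probe x sample intensities with optional detection p-values.

    ``values`` is a probes-by-samples DataFrame; ``scale`` records whether
    entries are linear intensities ("linear") or log2 units ("log2").
    ``probe_to_gene`` may be many-to-one; probes absent from the mapping are
    treated as unmapped.
    """

    values: pd.DataFrame
    samples: list[SampleDescriptor]
    probe_to_gene: dict[str, str] = field(default_factory=dict)
    detection_p: pd.DataFrame | None = None
    scale: str = "linear"

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample ids in sample list")
        if list(self.values.columns) != ids:
            raise FormatError(
                "matrix columns do not match sample descriptors: "
                f"{list(self.values.columns)} vs {ids}"
            )
        if not np.isfinite(self.values.to_numpy()).all():
            raise FormatError("expression values must be finite")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise FormatError(
                    f"detection_p shape {self.detection_p.shape} does not "
                    f"match values shape {self.values.shape}"
                )
            dp = self.detection_p.to_numpy()
            if ((dp < 0) | (dp > 1)).any():
                raise FormatError("detection p-values must lie in [0, 1]")
        wt = [s for s in self.samples if s.is_wildtype() and s.compartment is None]
        keys = [(s.cell_type, s.organ, s.replicate) for s in wt]
        if len(set(keys)) != len(keys):
            raise FormatError(
                "(cell_type, organ, replicate) not unique among wild-type samples"
            )
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")

    # -- convenience views --------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    def sample_frame(self) -> pd.DataFrame:
        """Sample sheet as a DataFrame indexed by sample_id."""
        rows = [asdict(s) for s in self.samples]
        return pd.DataFrame(rows).set_index("sample_id")

    def descriptor(self, sample_id: str) -> SampleDescriptor:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        dp = self.detection_p.loc[list(probes)] if self.detection_p is not None else None
        return ExpressionMatrix(
            values=self.values.loc[list(probes)],
            samples=list(self.samples),
            probe_to_gene=self.probe_to_gene,
            detection_p=dp,
            scale=self.scale,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = [s for s in self.samples if s.sample_id in set(sample_ids)]
        order = [s.sample_id for s in keep]
        dp = self.detection_p[order] if self.detection_p is not None else None
        return ExpressionMatrix(
            values=self.values[order],
            samples=keep,
            probe_to_gene=self.probe_to_gene,
            detection_p=dp,
            scale=self.scale,
        )


@dataclass
class ConditionProfile:
    """Gene x condition matrix of log2 means.

    Conditions are (cell_type, organ) pairs; the full factorial design has
    eight.  Columns are a pandas MultiIndex of those pairs.
    """

    means: pd.DataFrame

    def __post_init__(self):
        if not isinstance(self.means.columns, pd.MultiIndex):
            raise ValueError("ConditionProfile columns must be (cell_type, organ) pairs")
        if not np.isfinite(self.means.to_numpy()).all():
            raise FormatError("condition means must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.means.index)

    @property
    def conditions(self) -> list[tuple[str, str]]:
        return list(self.means.columns)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]  # insertion order kept; duplicates collapsed

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection:
    """Named gene sets plus the universe they are interpreted against."""

    def __init__(self, sets: Iterable[GeneSet], universe: Iterable[str] | None = None):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in self._sets:
                raise FormatError(f"duplicate gene-set name {gs.name!r}")
            self._sets[gs.name] = gs
        self.universe: frozenset[str] = frozenset(universe) if universe is not None else frozenset(
            g for gs in self._sets.values() for g in gs.members
        )

    def __iter__(self):
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set (and the universe) with ``universe``."""
        uni = frozenset(universe)
        sets = [
            GeneSet(gs.name, gs.description, tuple(g for g in gs.members if g in uni))
            for gs in self
        ]
        return GeneSetCollection(sets, universe=self.universe & uni if self.universe else uni)


# ---------------------------------------------------------------------------
# genomic intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLocation:
    """Gene interval, 0-based half-open, strand required."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval for {self.gene_id}: [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id} needs strand '+' or '-'")

    @property
    def tss(self) -> int:
        """Transcription start: left boundary on +, right boundary on -."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class LocusInterval:
    """Disease-locus interval, 0-based half-open, strandless."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval for {self.name}: [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PromoterSet:
    """Promoter sequences, all oriented 5'->3' toward the gene.

    The window covers ``upstream`` nt before and ``downstream`` nt after the
    TSS (default 1000/200).  Sequences clipped at a contig edge are listed in
    ``clipped``.
    """

    sequences: dict[str, str]
    upstream: int = 1000
    downstream: int = 200
    clipped: frozenset[str] = frozenset()

    def __post_init__(self):
        full = self.upstream + self.downstream
        for g, s in self.sequences.items():
            if len(s) > full:
                raise FormatError(f"promoter of {g} longer than window ({len(s)} > {full})")
            if len(s) < full and g not in self.clipped:
                raise FormatError(f"promoter of {g} short ({len(s)}) but not flagged clipped")
            if set(s) - set("ACGTN"):
                raise FormatError(f"promoter of {g} contains non-ACGTN characters")

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gene: str) -> str:
        return self.sequences[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.sequences

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)

    def subset(self, genes: Iterable[str]) -> "PromoterSet":
        genes = [g for g in genes if g in self.sequences]
        return PromoterSet(
            sequences={g: self.sequences[g] for g in genes},
            upstream=self.upstream,
            downstream=self.downstream,
            clipped=self.clipped & frozenset(genes),
        )


# ---------------------------------------------------------------------------
# planted ground truth (synthetic datasets)
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Record of every signal planted by the synthetic-data generator."""

    planted_markers: dict[str, set[str]] = field(default_factory=dict)
    planted_mirna_effects: dict[str, list[tuple[tuple[str, str], float]]] = field(default_factory=dict)
    planted_mirna_targets: dict[str, set[str]] = field(default_factory=dict)
    planted_motif: str = ""
    planted_motif_sites: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    planted_module: set[str] = field(default_factory=set)
    planted_locus_causal: dict[str, tuple[str, str]] = field(default_factory=dict)
    twirler_derepressed: set[str] = field(default_factory=set)
    twirler_downregulated: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "planted_markers": {k: sorted(v) for k, v in self.planted_markers.items()},
            "planted_mirna_effects": {
                k: [[list(cond), shift] for cond, shift in v]
                for k, v in self.planted_mirna_effects.items()
            },
            "planted_mirna_targets": {k: sorted(v) for k, v in self.planted_mirna_targets.items()},
            "planted_motif": self.planted_motif,
            "planted_motif_sites": {
                k: [[off, strand] for off, strand in v]
                for k, v in self.planted_motif_sites.items()
            },
            "planted_module": sorted(self.planted_module),
            "planted_locus_causal": {k: list(v) for k, v in self.planted_locus_causal.items()},
            "twirler_derepressed": sorted(self.twirler_derepressed),
            "twirler_downregulated": sorted(self.twirler_downregulated),
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            planted_markers={k: set(v) for k, v in obj["planted_markers"].items()},
            planted_mirna_effects={
                k: [(tuple(cond), shift) for cond, shift in v]
                for k, v in obj["planted_mirna_effects"].items()
            },
            planted_mirna_targets={k: set(v) for k, v in obj["planted_mirna_targets"].items()},
            planted_motif=obj["planted_motif"],
            planted_motif_sites={
                k: [(off, strand) for off, strand in v]
                for k, v in obj["planted_motif_sites"].items()
            },
            planted_module=set(obj["planted_module"]),
            planted_locus_causal={k: tuple(v) for k, v in obj["planted_locus_causal"].items()},
            twirler_derepressed=set(obj["twirler_derepressed"]),
            twirler_downregulated=set(obj["twirler_downregulated"]),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SHEET_REQUIRED = ("sample_id", "cell_type", "organ", "replicate")


def _read_sample_sheet(path: str | Path) -> dict[str, SampleDescriptor]:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SHEET_REQUIRED if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet {path} lacks columns: {missing}")
    out: dict[str, SampleDescriptor] = {}
    for _, row in sheet.iterrows():
        sid = row["sample_id"]
        if sid in out:
            raise FormatError(f"duplicate sample_id {sid!r} in sample sheet")
        geno = row.get("genotype")
        comp = row.get("compartment")
        out[sid] = SampleDescriptor(
            sample_id=sid,
            cell_type=row["cell_type"],
            organ=row["organ"],
            replicate=int(row["replicate"]),
            genotype=None if pd.isna(geno) or geno == "" else geno,
            compartment=None if pd.isna(comp) or comp == "" else comp,
        )
    return out


def _read_numeric_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    for col in bad:
        coerced = pd.to_numeric(df[col], errors="coerce")
        offenders = df.index[coerced.isna() & df[col].notna()]
        if len(offenders):
            raise FormatError(
                f"{path}: non-numeric value {df.loc[offenders[0], col]!r} "
                f"at row {offenders[0]!r}, column {col!r}"
            )
        df[col] = coerced
    return df


def read_expression(
    matrix_path: str | Path,
    sample_sheet_path: str | Path,
    detection_path: str | Path | None = None,
    probe_map_path: str | Path | None = None,
    scale: str = "linear",
) -> ExpressionMatrix:
    """Read an expression TSV (probe ids x sample ids) plus its sample sheet.

    Every matrix column must be described by the sheet; a detection-p TSV, if
    given, must have identical shape and labels.  An optional two-column TSV
    (probe_id, gene_id) supplies the probe-to-gene map.
    """
    values = _read_numeric_tsv(matrix_path)
    sheet = _read_sample_sheet(sample_sheet_path)
    unknown = [c for c in values.columns if c not in sheet]
    if unknown:
        raise FormatError(f"samples in matrix but not sample sheet: {unknown}")
    samples = [sheet[c] for c in values.columns]
    detection = None
    if detection_path is not None:
        detection = _read_numeric_tsv(detection_path)
        if list(detection.index) != list(values.index) or list(detection.columns) != list(values.columns):
            raise FormatError("detection-p matrix labels do not match expression matrix")
    probe_map: dict[str, str] = {}
    if probe_map_path is not None:
        pm = pd.read_csv(probe_map_path, sep="\t", header=None, dtype=str)
        if pm.shape[1] < 2:
            raise FormatError(f"probe map {probe_map_path} needs two columns")
        probe_map = dict(zip(pm.iloc[:, 0], pm.iloc[:, 1]))
    return ExpressionMatrix(values=values, samples=samples, probe_to_gene=probe_map,
                            detection_p=detection, scale=scale)


def write_expression(
    m: ExpressionMatrix,
    matrix_path: str | Path,
    sample_sheet_path: str | Path,
    detection_path: str | Path | None = None,
    probe_map_path: str | Path | None = None,
) -> None:
    m.values.to_csv(matrix_path, sep="\t", float_format="%.10g")
    sheet = m.sample_frame().reset_index()
    sheet.to_csv(sample_sheet_path, sep="\t", index=False)
    if detection_path is not None and m.detection_p is not None:
        m.detection_p.to_csv(detection_path, sep="\t", float_format="%.10g")
    if probe_map_path is not None and m.probe_to_gene:
        with open(probe_map_path, "w") as fh:
            for probe, gene in m.probe_to_gene.items():
                fh.write(f"{probe}\t{gene}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 2 fields")
            name, desc, *members = fields
            members = [g for g in members if g]
            seen: dict[str, None] = {}
            dups = []
            for g in members:
                if g in seen:
                    dups.append(g)
                seen[g] = None
            if dups:
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} lists duplicate members {sorted(set(dups))}; collapsed"
                )
            sets.append(GeneSet(name, desc, tuple(seen)))
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_bed(path: str | Path) -> list[GeneLocation | LocusInterval]:
    """Read a BED file; rows with a strand column become GeneLocations."""
    out: list[GeneLocation | LocusInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED line needs >=4 columns")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from e
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            if len(fields) >= 6 and fields[5] in ("+", "-"):
                out.append(GeneLocation(name, chrom, start, end, fields[5]))
            else:
                out.append(LocusInterval(name, chrom, start, end))
    return out


def write_bed(items: Sequence[GeneLocation | LocusInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for it in items:
            if isinstance(it, GeneLocation):
                fh.write(f"{it.chrom}\t{it.start}\t{it.end}\t{it.gene_id}\t0\t{it.strand}\n")
            else:
                fh.write(f"{it.chrom}\t{it.start}\t{it.end}\t{it.name}\n")


def read_network(path: str | Path) -> nx.Graph:
    """Read an undirected PPI edge list (two id columns per line)."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: edge line needs two columns")
            a, b = fields[0], fields[1]
            if a == b:
                continue  # self-loops carry no module information
            g.add_edge(a, b)
    return g


def write_network(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain FASTA reader returning upper-case sequences keyed by first token."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise FormatError(f"{path}: duplicate sequence name {name!r}")
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line.strip().upper())
            elif line.strip():
                raise FormatError(f"{path}: sequence data before first header")
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_promoters_fasta(path: str | Path, upstream: int = 1000, downstream: int = 200) -> PromoterSet:
    seqs = read_fasta(path)
    full = upstream + downstream
    clipped = frozenset(g for g, s in seqs.items() if len(s) < full)
    return PromoterSet(sequences=seqs, upstream=upstream, downstream=downstream, clipped=clipped)


def extract_promoters(
    genes: Sequence[GeneLocation],
    genome: str | Path,
    upstream: int = 1000,
    downstream: int = 200,
) -> PromoterSet:
    """Extract promoter windows around each TSS from a genome FASTA.

    Plus-strand genes yield the forward slice [TSS-upstream, TSS+downstream);
    minus-strand genes the reverse complement of [TSS-downstream, TSS+upstream),
    so every promoter reads 5'->3' toward its gene.  Windows running off a
    contig edge are clipped and flagged.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
    sequences: dict[str, str] = {}
    clipped: set[str] = set()
    for gene in genes:
        if gene.chrom not in fa:
            raise FormatError(f"genome lacks contig {gene.chrom!r} needed by {gene.gene_id}")
        contig_len = len(fa[gene.chrom])
        tss = gene.tss
        if gene.strand == "+":
            lo, hi = tss - upstream, tss + downstream
        else:
            lo, hi = tss - downstream, tss + upstream
        clo, chi = max(lo, 0), min(hi, contig_len)
        if clo >= chi:
            raise FormatError(f"promoter window of {gene.gene_id} falls outside contig")
        seq = str(fa[gene.chrom][clo:chi])
        if gene.strand == "-":
            seq = reverse_complement(seq)
        sequences[gene.gene_id] = seq
        if (clo, chi) != (lo, hi):
            clipped.add(gene.gene_id)
    return PromoterSet(sequences=sequences, upstream=upstream, downstream=downstream,
                       clipped=frozenset(clipped))
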