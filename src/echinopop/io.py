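"""Carriers for the three external data types and their file formats.

* :class:`SequencePanel` — aligned haploid sequences (FASTA + population map)
* :class:`GenotypePanel` — diploid microsatellite genotypes (GenePop, 3-digit)
* :class:`GeoDistanceMatrix` — pairwise sea distances between populations (CSV)

All loaders validate invariants at read time so that downstream statistics
never see an inconsistent panel.  The population map is a CSV with columns
``sample,population,region``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from echinopop.errors import (
    AlignmentError,
    GenePopFormatError,
    PopulationMapError,
    ValidationError,
)

_VALID_BASES = frozenset("ACGT-N")

MISSING = -1  # sentinel for a missing allele in GenotypePanel.alleles


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------

def read_population_map(path) -> pd.DataFrame:
    """Read a ``sample,population,region`` CSV; every column required."""
    df = pd.read_csv(path, dtype=str)
    required = {"sample", "population", "region"}
    if not required.issubset(df.columns):
        raise PopulationMapError(
            f"population map needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise PopulationMapError(f"duplicate sample id in population map: {dup!r}")
    # a population must sit in exactly one region
    reg = df.groupby("population")["region"].nunique()
    if (reg > 1).any():
        bad = reg[reg > 1].index[0]
        raise PopulationMapError(f"population {bad!r} assigned to more than one region")
    return df


def write_population_map(df: pd.DataFrame, path) -> None:
    df[["sample", "population", "region"]].to_csv(path, index=False)


def _maps_from_df(df: pd.DataFrame):
    population_of = dict(zip(df["sample"], df["population"]))
    region_of = dict(
        df.drop_duplicates("population")[["population", "region"]].itertuples(index=False)
    )
    return population_of, region_of


# ---------------------------------------------------------------------------
# SequencePanel
# ---------------------------------------------------------------------------

@dataclass
class SequencePanel:
    """Aligned haploid sequences with a population/region assignment.

    ``sequences[i]`` belongs to ``sample_ids[i]``.  All sequences share one
    alignment length ``L`` over the alphabet {A,C,G,T,-,N}.
    """

    sample_ids: list[str]
    sequences: list[str]
    population_of: dict[str, str]
    region_of: dict[str, str]

    def __post_init__(self):
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise ValidationError("sample_ids and sequences differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in panel")
        if not self.sequences:
            raise ValidationError("empty sequence panel")
        L = len(self.sequences[0])
        if L == 0:
            raise AlignmentError("zero-length alignment")
        for sid, seq in zip(self.sample_ids, self.sequences):
            if len(seq) != L:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(seq)}, expected {L}"
                )
            bad = set(seq) - _VALID_BASES
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} contains invalid symbols {sorted(bad)} "
                    "(IUPAC ambiguity codes other than N are rejected)"
                )
        for sid in self.sample_ids:
            if sid not in self.population_of:
                raise PopulationMapError(f"sample {sid!r} missing from population map")
        for pop in set(self.population_of[s] for s in self.sample_ids):
            if pop not in self.region_of:
                raise PopulationMapError(f"population {pop!r} has no region")

    # -- convenience --------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def L(self) -> int:
        return len(self.sequences[0])

    def populations(self) -> list[str]:
        """Populations in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.population_of[s], None)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return [s for s in self.sample_ids if self.population_of[s] == population]

    def subset(self, populations=None, samples=None) -> "SequencePanel":
        if samples is None:
            pops = set(populations)
            samples = [s for s in self.sample_ids if self.population_of[s] in pops]
        keep = set(samples)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep]
        ids = [self.sample_ids[i] for i in idx]
        return SequencePanel(
            sample_ids=ids,
            sequences=[self.sequences[i] for i in idx],
            population_of={s: self.population_of[s] for s in ids},
            region_of=dict(self.region_of),
        )

    def matrix(self) -> np.ndarray:
        """Alignment as an (n, L) array of single-character strings."""
        return np.array([list(s) for s in self.sequences], dtype="U1")

    def __eq__(self, other):
        return (
            isinstance(other, SequencePanel)
            and self.sample_ids == other.sample_ids
            and self.sequences == other.sequences
            and {s: self.population_of[s] for s in self.sample_ids}
            == {s: other.population_of[s] for s in other.sample_ids}
        )


def read_sequence_panel(fasta_path, popmap_path) -> SequencePanel:
    """Load an aligned FASTA plus its population map into a validated panel."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    df = read_population_map(popmap_path)
    population_of, region_of = _maps_from_df(df)
    ids = [r.id for r in records]
    for sid in ids:
        if sid not in population_of:
            raise PopulationMapError(f"FASTA sample {sid!r} not in population map")
    seqs = [str(r.seq).upper() for r in records]
    return SequencePanel(ids, seqs, population_of, region_of)


def write_sequence_panel(panel: SequencePanel, fasta_path, popmap_path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(panel.sample_ids, panel.sequences)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        (s, panel.population_of[s], panel.region_of[panel.population_of[s]])
        for s in panel.sample_ids
    ]
    write_population_map(
        pd.DataFrame(rows, columns=["sample", "population", "region"]), popmap_path
    )


# ---------------------------------------------------------------------------
# GenotypePanel
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Diploid allele-size genotypes (individuals x loci x 2), sizes in bp.

    ``alleles`` is an integer array with :data:`MISSING` (-1) marking absent
    data; both gene copies of a genotype are present or both missing.
    ``motif_length_of`` gives the repeat-unit length per locus (needed for
    M-ratio analyses).
    """

    sample_ids: list[str]
    loci_ids: list[str]
    alleles: np.ndarray
    population_of: dict[str, str]
    region_of: dict[str, str]
    motif_length_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=int)
        self.validate()

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.loci_ids)) != len(self.loci_ids):
            raise ValidationError("duplicate locus ids")
        if self.alleles.shape != (len(self.sample_ids), len(self.loci_ids), 2):
            raise ValidationError(
                f"alleles shape {self.alleles.shape} != "
                f"({len(self.sample_ids)}, {len(self.loci_ids)}, 2)"
            )
        a, b = self.alleles[..., 0], self.alleles[..., 1]
        if ((a == MISSING) != (b == MISSING)).any():
            raise ValidationError("half-missing genotype (one allele present)")
        present = self.alleles[self.alleles != MISSING]
        if present.size and (present <= 0).any():
            raise ValidationError("allele sizes must be positive integers")
        for sid in self.sample_ids:
            if sid not in self.population_of:
                raise PopulationMapError(f"sample {sid!r} missing from population map")
        for pop in set(self.population_of[s] for s in self.sample_ids):
            if pop not in self.region_of:
                raise PopulationMapError(f"population {pop!r} has no region")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci_ids)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.population_of[s], None)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return [s for s in self.sample_ids if self.population_of[s] == population]

    def population_alleles(self, population: str, locus: str) -> np.ndarray:
        """All non-missing gene copies for one population at one locus."""
        li = self.loci_ids.index(locus)
        idx = [i for i, s in enumerate(self.sample_ids) if self.population_of[s] == population]
        vals = self.alleles[idx, li, :].ravel()
        return vals[vals != MISSING]

    def genotypes(self, population: str, locus: str) -> np.ndarray:
        """Complete genotypes (k, 2) for one population at one locus."""
        li = self.loci_ids.index(locus)
        idx = [i for i, s in enumerate(self.sample_ids) if self.population_of[s] == population]
        g = self.alleles[idx, li, :]
        return g[g[:, 0] != MISSING]

    def subset(self, populations) -> "GenotypePanel":
        pops = set(populations)
        idx = [i for i, s in enumerate(self.sample_ids) if self.population_of[s] in pops]
        ids = [self.sample_ids[i] for i in idx]
        return GenotypePanel(
            sample_ids=ids,
            loci_ids=list(self.loci_ids),
            alleles=self.alleles[idx],
            population_of={s: self.population_of[s] for s in ids},
            region_of=dict(self.region_of),
            motif_length_of=dict(self.motif_length_of),
        )

    def __eq__(self, other):
        return (
            isinstance(other, GenotypePanel)
            and self.sample_ids == other.sample_ids
            and self.loci_ids == other.loci_ids
            and np.array_equal(self.alleles, other.alleles)
            and {s: self.population_of[s] for s in self.sample_ids}
            == {s: other.population_of[s] for s in other.sample_ids}
        )


def read_motif_table(path) -> dict[str, int]:
    df = pd.read_csv(path)
    if not {"locus", "motif_length"}.issubset(df.columns):
        raise ValidationError("motif table needs columns locus,motif_length")
    return dict(zip(df["locus"].astype(str), df["motif_length"].astype(int)))


def read_genotype_panel(genepop_path, popmap_path, motif_table=None) -> GenotypePanel:
    """Parse a GenePop file (3-digit allele codes, 000 = missing).

    ``motif_table`` may be a ``{locus: motif_length}`` dict or a CSV path with
    columns ``locus,motif_length``.
    """
    with open(genepop_path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 3:
        raise GenePopFormatError("GenePop file too short")
    # line 0: title.  Then locus names until the first 'Pop' line; locus names
    # may also be comma-separated on a single line.
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        loci.extend(x.strip() for x in body[i].split(",") if x.strip())
        i += 1
    if i == len(body):
        raise GenePopFormatError("no 'Pop' line found")
    sample_ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_index: list[int] = []
    current_pop = -1
    for ln in body[i:]:
        if ln.strip().lower() == "pop":
            current_pop += 1
            continue
        if "," not in ln:
            raise GenePopFormatError(f"genotype row without ',' separator: {ln!r}")
        name, geno = ln.split(",", 1)
        codes = geno.split()
        if len(codes) != len(loci):
            raise GenePopFormatError(
                f"sample {name.strip()!r} has {len(codes)} genotypes, "
                f"expected {len(loci)} (locus count mismatch)"
            )
        pair_row = []
        for locus, code in zip(loci, codes):
            if not re.fullmatch(r"\d{6}", code):
                if re.fullmatch(r"\d{4}", code):
                    raise GenePopFormatError(
                        f"2-digit allele codes not supported (locus {locus}, "
                        f"code {code!r}); use the 3-digit GenePop dialect"
                    )
                raise GenePopFormatError(
                    f"malformed genotype code {code!r} at locus {locus}"
                )
            a, b = int(code[:3]), int(code[3:])
            if (a == 0) != (b == 0):
                raise GenePopFormatError(
                    f"half-missing genotype {code!r} at locus {locus}"
                )
            pair_row.append((a or MISSING, b or MISSING))
        sample_ids.append(name.strip())
        rows.append(pair_row)
        pop_index.append(current_pop)
    df = read_population_map(popmap_path)
    population_of, region_of = _maps_from_df(df)
    for sid in sample_ids:
        if sid not in population_of:
            raise PopulationMapError(f"GenePop sample {sid!r} not in population map")
    if motif_table is None:
        motifs = {}
    elif isinstance(motif_table, dict):
        motifs = dict(motif_table)
    else:
        motifs = read_motif_table(motif_table)
    return GenotypePanel(
        sample_ids=sample_ids,
        loci_ids=loci,
        alleles=np.array(rows, dtype=int),
        population_of=population_of,
        region_of=region_of,
        motif_length_of=motifs,
    )


def write_genotype_panel(panel: GenotypePanel, genepop_path, popmap_path=None,
                         title="echinopop export") -> None:
    """Write 3-digit GenePop, grouping consecutive samples by population."""
    present = panel.alleles[panel.alleles != MISSING]
    if present.size and present.max() > 999:
        raise GenePopFormatError("allele size > 999 cannot be 3-digit encoded")
    with open(genepop_path, "w") as fh:
        fh.write(title + "\n")
        for locus in panel.loci_ids:
            fh.write(locus + "\n")
        last_pop = None
        for i, sid in enumerate(panel.sample_ids):
            pop = panel.population_of[sid]
            if pop != last_pop:
                fh.write("Pop\n")
                last_pop = pop
            codes = []
            for j in range(panel.n_loci):
                a, b = panel.alleles[i, j]
                a = 0 if a == MISSING else a
                b = 0 if b == MISSING else b
                codes.append(f"{a:03d}{b:03d}")
            fh.write(f"{sid} , " + " ".join(codes) + "\n")
    if popmap_path is not None:
        rows = [
            (s, panel.population_of[s], panel.region_of[panel.population_of[s]])
            for s in panel.sample_ids
        ]
        write_population_map(
            pd.DataFrame(rows, columns=["sample", "population", "region"]), popmap_path
        )


# ---------------------------------------------------------------------------
# GeoDistanceMatrix
# ---------------------------------------------------------------------------

@dataclass
class GeoDistanceMatrix:
    """Symmetric matrix of sea distances (km) between populations."""

    populations: list[str]
    distances: np.ndarray

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.validate()

    def validate(self) -> None:
        k = len(self.populations)
        if self.distances.shape != (k, k):
            raise ValidationError("distance matrix shape does not match populations")
        if (self.distances < 0).any():
            raise ValidationError("negative distance")
        if not np.allclose(np.diag(self.distances), 0):
            raise ValidationError("nonzero diagonal in distance matrix")
        if not np.allclose(self.distances, self.distances.T, atol=1e-9):
            raise ValidationError("distance matrix not symmetric")
        # symmetrise away numerical asymmetry below tolerance
        self.distances = (self.distances + self.distances.T) / 2.0

    def submatrix(self, populations) -> np.ndarray:
        idx = [self.populations.index(p) for p in populations]
        return self.distances[np.ix_(idx, idx)]


def read_geo_distances(csv_path) -> GeoDistanceMatrix:
    df = pd.read_csv(csv_path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError("row and column population labels differ")
    return GeoDistanceMatrix(list(map(str, df.index)), df.to_numpy(dtype=float))


def write_geo_distances(matrix: GeoDistanceMatrix, csv_path) -> None:
    pd.DataFrame(
        matrix.distances, index=matrix.populations, columns=matrix.populations
    ).to_csv(csv_path)
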