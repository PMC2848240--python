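"""Genotype data model and PLINK-text I/O.

Genotypes are stored as an (individuals x markers) int8 matrix of codes:
``HOM_A1`` (0), ``HET`` (1), ``HOM_A2`` (2) and ``MISSING`` (-1).  Allele 1
is, by default, the first allele observed at each marker in the PED file;
only allele *frequencies*, never labels, enter any estimator downstream.
Genetic positions are kept in Morgans everywhere (PLINK MAP column 3 is
read as centiMorgans and divided by 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

HOM_A1 = np.int8(0)
HET = np.int8(1)
HOM_A2 = np.int8(2)
MISSING = np.int8(-1)

#: number of allele-1 copies carried by each genotype code (MISSING -> 0)
_A1_DOSAGE = np.array([2, 1, 0], dtype=np.int64)


class PlinkParseError(ValueError):
    """Raised when a PED/MAP file violates the text dialect."""


@dataclass
class MarkerMap:
    """Ordered autosomal marker map.

    Parameters
    ----------
    marker_id : array of str
    chromosome : array of int (1..22)
    genetic_pos : array of float, Morgans, non-decreasing within chromosome
    freq_a1 : array of float or None
        Frequency of allele 1; NaN where unknown/undefined.
    bp_pos : array of int or None
        Physical positions, carried only for MAP round-tripping.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    genetic_pos: np.ndarray
    freq_a1: np.ndarray | None = None
    bp_pos: np.ndarray | None = None
    n_position_ties: int = 0

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=np.float64)
        if self.freq_a1 is not None:
            self.freq_a1 = np.asarray(self.freq_a1, dtype=np.float64)
        if self.bp_pos is not None:
            self.bp_pos = np.asarray(self.bp_pos, dtype=np.int64)
        if np.any(self.genetic_pos < 0):
            raise ValueError("genetic positions must be non-negative")
        self._sort_within_chromosomes()

    def _sort_within_chromosomes(self) -> None:
        order = np.lexsort((np.arange(len(self)), self.genetic_pos, self.chromosome))
        if not np.array_equal(order, np.arange(len(self))):
            self.marker_id = self.marker_id[order]
            self.chromosome = self.chromosome[order]
            self.genetic_pos = self.genetic_pos[order]
            if self.freq_a1 is not None:
                self.freq_a1 = self.freq_a1[order]
            if self.bp_pos is not None:
                self.bp_pos = self.bp_pos[order]
        same_chrom = self.chromosome[1:] == self.chromosome[:-1]
        self.n_position_ties = int(
            np.sum(same_chrom & (self.genetic_pos[1:] == self.genetic_pos[:-1]))
        )

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> np.ndarray:
        """Unique chromosomes, in map order."""
        return pd.unique(self.chromosome)

    def chrom_slices(self) -> list[slice]:
        """Contiguous marker index ranges, one per chromosome in map order."""
        out: list[slice] = []
        start = 0
        for i in range(1, len(self) + 1):
            if i == len(self) or self.chromosome[i] != self.chromosome[start]:
                out.append(slice(start, i))
                start = i
        return out

    def informative_mask(self) -> np.ndarray:
        """Markers whose allele-1 frequency lies strictly in (0, 1).

        Monomorphic and frequency-undefined markers are excluded from every
        likelihood-based estimator.
        """
        if self.freq_a1 is None:
            raise ValueError("marker map carries no allele frequencies")
        with np.errstate(invalid="ignore"):
            return (self.freq_a1 > 0.0) & (self.freq_a1 < 1.0)

    def to_frame(self) -> pd.DataFrame:
        d = {
            "marker_id": self.marker_id,
            "chromosome": self.chromosome,
            "genetic_pos": self.genetic_pos,
        }
        if self.freq_a1 is not None:
            d["freq_a1"] = self.freq_a1
        return pd.DataFrame(d)

    def subset(self, index: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            self.marker_id[index],
            self.chromosome[index],
            self.genetic_pos[index],
            None if self.freq_a1 is None else self.freq_a1[index],
            None if self.bp_pos is None else self.bp_pos[index],
        )


@dataclass
class FrequencySource:
    """Per-marker allele-1 frequencies, either sample-estimated or provided.

    ``n_nonmissing`` (only meaningful in ``sample_estimated`` mode) is the
    number of individuals with a call at each marker; it drives the
    2N/(2N-1) small-sample correction in the moment estimator.
    """

    mode: str  # "sample_estimated" | "provided"
    values: np.ndarray
    n_nonmissing: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("sample_estimated", "provided"):
            raise ValueError(f"unknown frequency mode {self.mode!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.n_nonmissing is not None:
            self.n_nonmissing = np.asarray(self.n_nonmissing, dtype=np.int64)

    @property
    def undefined_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)


@dataclass
class GenotypeDataset:
    """Individuals x markers genotype calls with a marker map."""

    individuals: list[str]
    markers: MarkerMap
    calls: np.ndarray
    allele_symbols: list[tuple[str, str]] | None = None
    _ind_missing: np.ndarray | None = field(default=None, repr=False)
    _marker_missing: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def individual_missingness(self) -> np.ndarray:
        if self._ind_missing is None or len(self._ind_missing) != self.n_individuals:
            self._ind_missing = np.mean(self.calls == MISSING, axis=1)
        return self._ind_missing

    def marker_missingness(self) -> np.ndarray:
        if self._marker_missing is None or len(self._marker_missing) != self.n_markers:
            self._marker_missing = np.mean(self.calls == MISSING, axis=0)
        return self._marker_missing

    def genotype_counts(self) -> pd.DataFrame:
        """Per-marker counts of hom_a1 / het / hom_a2 / missing."""
        return pd.DataFrame(
            {
                "n_hom_a1": np.sum(self.calls == HOM_A1, axis=0),
                "n_het": np.sum(self.calls == HET, axis=0),
                "n_hom_a2": np.sum(self.calls == HOM_A2, axis=0),
                "n_missing": np.sum(self.calls == MISSING, axis=0),
            },
            index=self.markers.marker_id,
        )

    def subset(
        self,
        individuals: np.ndarray | None = None,
        markers: np.ndarray | None = None,
    ) -> "GenotypeDataset":
        ind_idx = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        mk_idx = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        syms = self.allele_symbols
        if syms is not None:
            syms = [syms[i] for i in mk_idx]
        return GenotypeDataset(
            [self.individuals[i] for i in ind_idx],
            self.markers.subset(mk_idx),
            self.calls[np.ix_(ind_idx, mk_idx)],
            syms,
        )


def estimate_frequencies(dataset: GenotypeDataset) -> FrequencySource:
    """Sample allele-1 frequencies: (2*n_hom_a1 + n_het) / (2*n_nonmissing).

    Markers with no non-missing calls get NaN (undefined) frequency.
    """
    if dataset.n_individuals == 0 or dataset.n_markers == 0:
        raise ValueError("dataset is empty")
    counts = dataset.genotype_counts()
    n_nonmiss = (counts.n_hom_a1 + counts.n_het + counts.n_hom_a2).to_numpy()
    a1 = (2 * counts.n_hom_a1 + counts.n_het).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(n_nonmiss > 0, a1 / (2.0 * n_nonmiss), np.nan)
    return FrequencySource("sample_estimated", freq, n_nonmiss)


# ---------------------------------------------------------------------------
# PLINK text dialect
# ---------------------------------------------------------------------------

def read_map(map_path: str | Path) -> MarkerMap:
    """Read a 4-column PLINK MAP file (chrom, id, genetic pos in cM, bp)."""
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PlinkParseError(
                    f"{map_path}: line {lineno}: expected 4 columns, got {len(parts)}"
                )
            rows.append(parts)
    chrom = np.array([int(r[0]) for r in rows])
    ids = np.array([r[1] for r in rows], dtype=object)
    gpos_cm = np.array([float(r[2]) for r in rows])
    bp = np.array([int(r[3]) for r in rows])
    return MarkerMap(ids, chrom, gpos_cm / 100.0, None, bp)


def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    reference_alleles: dict[str, str] | None = None,
) -> GenotypeDataset:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeDataset`.

    Allele 1 at each marker is the first non-missing allele observed in the
    PED file, unless ``reference_alleles`` maps the marker id to an explicit
    allele-1 symbol.  The pair "0 0" is missing.  More than two distinct
    alleles at a marker is an error.
    """
    markers = read_map(map_path)
    n_mark = len(markers)
    # MAP may have been re-sorted on load; PED columns follow MAP file order
    file_ids = _map_file_ids(map_path)
    col_of_marker = {mid: j for j, mid in enumerate(file_ids)}
    perm = np.array([col_of_marker[mid] for mid in markers.marker_id])

    individuals: list[str] = []
    allele1: list[str | None] = [None] * n_mark
    allele2: list[str | None] = [None] * n_mark
    if reference_alleles:
        for j, mid in enumerate(markers.marker_id):
            if mid in reference_alleles:
                allele1[j] = reference_alleles[mid]
    call_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_mark:
                raise PlinkParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_mark} fields "
                    f"(6 + 2x{n_mark}), got {len(parts)}"
                )
            individuals.append(parts[1])
            row = np.full(n_mark, MISSING, dtype=np.int8)
            for j in range(n_mark):
                c = 6 + 2 * perm[j]
                a, b = parts[c], parts[c + 1]
                if a == "0" or b == "0":
                    if a != b:
                        raise PlinkParseError(
                            f"{ped_path}: line {lineno}: half-missing genotype at "
                            f"marker {markers.marker_id[j]}"
                        )
                    continue
                code = 0
                for al in (a, b):
                    if allele1[j] is None:
                        allele1[j] = al
                    if al == allele1[j]:
                        continue
                    if allele2[j] is None:
                        allele2[j] = al
                    if al != allele2[j]:
                        raise PlinkParseError(
                            f"marker {markers.marker_id[j]}: more than 2 alleles "
                            f"({allele1[j]}, {allele2[j]}, {al})"
                        )
                    code += 1
                row[j] = code  # 0=hom_a1, 1=het, 2=hom_a2
            call_rows.append(row)
    symbols = [
        (a1 if a1 is not None else "1", a2 if a2 is not None else "2")
        for a1, a2 in zip(allele1, allele2)
    ]
    calls = np.vstack(call_rows) if call_rows else np.empty((0, n_mark), dtype=np.int8)
    return GenotypeDataset(individuals, markers, calls, symbols)


def _map_file_ids(map_path: str | Path) -> list[str]:
    ids = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                ids.append(parts[1])
    return ids


def write_plink_text(
    dataset: GenotypeDataset, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a dataset back out as PLINK text PED/MAP (cM in MAP column 3)."""
    m = dataset.markers
    bp = m.bp_pos if m.bp_pos is not None else np.rint(m.genetic_pos * 1e8).astype(np.int64)
    with open(map_path, "w") as fh:
        for j in range(len(m)):
            fh.write(
                f"{m.chromosome[j]}\t{m.marker_id[j]}\t{m.genetic_pos[j] * 100.0:.6g}\t{bp[j]}\n"
            )
    syms = dataset.allele_symbols or [("1", "2")] * dataset.n_markers
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(dataset.individuals):
            fields = [iid, iid, "0", "0", "0", "-9"]
            row = dataset.calls[i]
            for j in range(dataset.n_markers):
                a1, a2 = syms[j]
                g = row[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == HOM_A1:
                    fields += [a1, a1]
                elif g == HET:
                    fields += [a1, a2]
                else:
                    fields += [a2, a2]
            fh.write(" ".join(fields) + "\n")


def write_frequency_tsv(markers: MarkerMap, freqs: FrequencySource, path: str | Path) -> None:
    pd.DataFrame(
        {"marker_id": markers.marker_id, "freq_a1": freqs.values}
    ).to_csv(path, sep="\t", index=False)


def read_frequency_tsv(path: str | Path, markers: MarkerMap) -> FrequencySource:
    """Read a (marker_id, freq_a1) TSV as a provided-frequency source."""
    df = pd.read_csv(path, sep="\t").set_index("marker_id")
    vals = df["freq_a1"].reindex(markers.marker_id).to_numpy()
    return FrequencySource("provided", vals)
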