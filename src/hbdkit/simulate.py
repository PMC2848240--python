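"""Gene-dropping simulation on consanguineous pedigrees.

Founder haplotypes receive unique integer labels which are transmitted
through the pedigree by meioses with Haldane (no-interference) crossovers:
the number of crossovers per chromosome per meiosis is Poisson in its
genetic length, crossover positions are uniform, and each chromosome's
starting parental strand is chosen at random.  Tracking labels down to the
proband makes homozygosity-by-descent exact: a marker is HBD iff the
proband's two labels coincide.  Alleles are then dropped onto founder
haplotypes independently per marker (linkage equilibrium), so HBD markers
are homozygous by construction.

The canonical scenarios are offspring of first, second and third cousins,
whose path-counting inbreeding coefficients are 1/16, 1/64 and 1/256.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import HET, HOM_A1, HOM_A2, GenotypeDataset, MarkerMap


@dataclass
class Pedigree:
    """Members are (id, father_id, mother_id); founders have (None, None)."""

    members: list[tuple[str, str | None, str | None]]
    proband_id: str

    def __post_init__(self) -> None:
        ids = [m[0] for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate member ids")
        known = set(ids)
        for mid, fa, mo in self.members:
            if (fa is None) != (mo is None):
                raise ValueError(f"{mid}: must have both parents or neither")
            for p in (fa, mo):
                if p is not None and p not in known:
                    raise ValueError(f"{mid}: unknown parent {p}")
        if self.proband_id not in known:
            raise ValueError("proband not in pedigree")
        self._order = self._toposort()

    def _toposort(self) -> list[str]:
        parents = {m[0]: (m[1], m[2]) for m in self.members}
        seen: dict[str, int] = {}

        def visit(mid: str, stack: set[str]) -> None:
            if mid in seen:
                return
            if mid in stack:
                raise ValueError("pedigree contains a cycle")
            stack.add(mid)
            fa, mo = parents[mid]
            if fa is not None:
                visit(fa, stack)
                visit(mo, stack)
            stack.discard(mid)
            seen[mid] = len(seen)

        for m in self.members:
            visit(m[0], set())
        return sorted(parents, key=seen.__getitem__)

    @property
    def founders(self) -> list[str]:
        return [m[0] for m in self.members if m[1] is None]

    def parents_of(self, mid: str) -> tuple[str | None, str | None]:
        for m in self.members:
            if m[0] == mid:
                return m[1], m[2]
        raise KeyError(mid)

    def kinship(self, a: str, b: str) -> float:
        """Recursive kinship coefficient phi(a, b)."""
        order = {mid: i for i, mid in enumerate(self._order)}
        parents = {m[0]: (m[1], m[2]) for m in self.members}
        cache: dict[tuple[str, str], float] = {}

        def phi(x: str, y: str) -> float:
            if order[x] < order[y]:
                x, y = y, x
            key = (x, y)
            if key in cache:
                return cache[key]
            fa, mo = parents[x]
            if x == y:
                v = 0.5 if fa is None else 0.5 * (1.0 + phi(fa, mo))
            elif fa is None:
                v = 0.0  # x is a founder and not an ancestor of y
            else:
                v = 0.5 * (phi(fa, y) + phi(mo, y))
            cache[key] = v
            return v

        return phi(a, b)

    def expected_inbreeding(self) -> float:
        """Path-counting F of the proband = kinship of its parents."""
        fa, mo = self.parents_of(self.proband_id)
        if fa is None:
            return 0.0
        return self.kinship(fa, mo)


def build_cousin_pedigree(degree: int, n_probands: int = 1) -> Pedigree:
    """Pedigree whose proband's parents are first/second/third cousins.

    ``degree`` 1, 2 or 3 gives expected proband F of 1/16, 1/64, 1/256.
    With ``n_probands`` > 1 the cousin couple has that many children
    (named ``proband``, ``proband_2``, ...) — used for sibling analyses;
    ``proband_id`` remains the first child.
    """
    if degree not in (1, 2, 3):
        raise ValueError(f"unsupported cousin degree {degree}")
    members: list[tuple[str, str | None, str | None]] = [
        ("anc_f", None, None),
        ("anc_m", None, None),
        ("sib_a0", "anc_f", "anc_m"),
        ("sib_b0", "anc_f", "anc_m"),
    ]
    last_a, last_b = "sib_a0", "sib_b0"
    # each extra generation of descent turns k-th cousins into (k+1)-th
    for g in range(degree):
        for side in ("a", "b"):
            last = last_a if side == "a" else last_b
            spouse = f"sp_{side}{g}"
            child = f"desc_{side}{g + 1}"
            members.append((spouse, None, None))
            members.append((child, last, spouse))
            if side == "a":
                last_a = child
            else:
                last_b = child
    for k in range(n_probands):
        name = "proband" if k == 0 else f"proband_{k + 1}"
        members.append((name, last_a, last_b))
    return Pedigree(members, "proband")


@dataclass
class SimMap:
    """A synthetic linkage-equilibrium marker map plus its provenance.

    Defaults emulate a pruned 10K genotyping array: 4,849 markers evenly
    spaced at 0.008 M (0.8 cM) over 22 equal-length chromosomes, allele-1
    frequencies i.i.d. Uniform(0.05, 0.95) (equivalently MAF ~ U(0.05, 0.5)).
    """

    markers: MarkerMap
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def chrom_lengths(self) -> np.ndarray:
        """Genetic length per chromosome (Morgans) = n_markers * spacing."""
        spacing = self.params["spacing_morgans"]
        return np.array(
            [(sl.stop - sl.start) * spacing for sl in self.markers.chrom_slices()]
        )


def make_sim_map(
    n_markers: int = 4849,
    spacing_morgans: float = 0.008,
    n_chromosomes: int = 22,
    freq_sampler=None,
    seed: int | np.random.SeedSequence | None = 0,
) -> SimMap:
    """Lay ``n_markers`` uniformly over equal-length chromosomes.

    ``freq_sampler(rng, n)`` draws allele-1 frequencies; the default is
    Uniform(0.05, 0.95).  The sampler spec and all parameters are recorded
    in ``SimMap.params`` for output provenance.
    """
    if n_markers < 1 or spacing_morgans <= 0 or n_chromosomes < 1:
        raise ValueError("n_markers >= 1, spacing > 0, n_chromosomes >= 1 required")
    rng = np.random.default_rng(seed)
    sampler_name = "uniform(0.05,0.95)"
    if freq_sampler is None:
        freq_sampler = lambda r, n: r.uniform(0.05, 0.95, n)  # noqa: E731
    else:
        sampler_name = getattr(freq_sampler, "__name__", repr(freq_sampler))
    base = n_markers // n_chromosomes
    extra = n_markers % n_chromosomes
    counts = np.array([base + (1 if c < extra else 0) for c in range(n_chromosomes)])
    counts = counts[counts > 0]
    chrom = np.repeat(np.arange(1, len(counts) + 1), counts)
    pos = np.concatenate([np.arange(k) * spacing_morgans for k in counts])
    ids = np.array([f"snp{i + 1}" for i in range(n_markers)], dtype=object)
    freqs = freq_sampler(rng, n_markers)
    markers = MarkerMap(ids, chrom, pos, freqs)
    return SimMap(
        markers,
        params={
            "n_markers": n_markers,
            "spacing_morgans": spacing_morgans,
            "n_chromosomes": int(len(counts)),
            "freq_sampler": sampler_name,
            "seed": repr(seed),
        },
    )


@dataclass
class HBDTrack:
    """Ground-truth per-marker autozygosity of a simulated proband."""

    hbd: np.ndarray  # bool per marker
    f_true: float

    def __post_init__(self) -> None:
        self.hbd = np.asarray(self.hbd, dtype=bool)


def hbd_track(label_pair: tuple[np.ndarray, np.ndarray]) -> HBDTrack:
    """HBD at a marker = the proband's two founder labels coincide."""
    l1, l2 = label_pair
    if l1.shape != l2.shape:
        raise ValueError("label sequences differ in length")
    hbd = l1 == l2
    return HBDTrack(hbd, float(np.mean(hbd)))


def _meiosis(
    hap0: np.ndarray,
    hap1: np.ndarray,
    pos: np.ndarray,
    chrom_index: np.ndarray,
    chrom_offsets: np.ndarray,
    chrom_lengths: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete: Haldane crossovers, independent per chromosome.

    ``pos`` is a genome-wide coordinate (per-chromosome position plus a
    cumulative offset), valid because the Poisson crossover process is run
    independently per chromosome and only crossover *counts before a
    marker on the same chromosome* matter.
    """
    n_chrom = len(chrom_lengths)
    n_cross = rng.poisson(chrom_lengths)
    total = int(n_cross.sum())
    if total:
        which = np.repeat(np.arange(n_chrom), n_cross)
        xpos = chrom_offsets[which] + rng.random(total) * chrom_lengths[which]
        xpos.sort()
        parity = np.searchsorted(xpos, pos, side="right") & 1
    else:
        parity = np.zeros(len(pos), dtype=np.intp)
    start = rng.integers(0, 2, n_chrom)
    strand = start[chrom_index] ^ parity
    return np.where(strand == 0, hap0, hap1)


class GeneDropper:
    """Drops founder labels through a pedigree over a fixed map.

    Precomputes genome-wide coordinates once; ``drop(rng)`` then simulates
    every meiosis and returns the label haplotype pair of each requested
    individual (by default just the proband).
    """

    def __init__(self, pedigree: Pedigree, sim_map: SimMap, targets: list[str] | None = None):
        self.pedigree = pedigree
        self.sim_map = sim_map
        self.targets = targets or [pedigree.proband_id]
        m = sim_map.markers
        slices = m.chrom_slices()
        self._chrom_lengths = sim_map.chrom_lengths
        offsets = np.concatenate([[0.0], np.cumsum(self._chrom_lengths)[:-1]])
        self._chrom_offsets = offsets
        chrom_index = np.empty(len(m), dtype=np.intp)
        pos = np.empty(len(m))
        for c, sl in enumerate(slices):
            chrom_index[sl] = c
            pos[sl] = m.genetic_pos[sl] - m.genetic_pos[sl.start] + offsets[c]
        self._chrom_index = chrom_index
        self._pos = pos
        self._founders = self.pedigree.founders
        self._label_of = {fid: 2 * i for i, fid in enumerate(self._founders)}

    @property
    def n_founder_haplotypes(self) -> int:
        return 2 * len(self._founders)

    def drop(self, rng: np.random.Generator) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        n = len(self.sim_map)
        haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for fid in self._founders:
            base = self._label_of[fid]
            haps[fid] = (
                np.full(n, base, dtype=np.int32),
                np.full(n, base + 1, dtype=np.int32),
            )
        for mid in self.pedigree._order:
            if mid in haps:
                continue
            fa, mo = self.pedigree.parents_of(mid)
            haps[mid] = (
                _meiosis(*haps[fa], self._pos, self._chrom_index,
                         self._chrom_offsets, self._chrom_lengths, rng),
                _meiosis(*haps[mo], self._pos, self._chrom_index,
                         self._chrom_offsets, self._chrom_lengths, rng),
            )
        return {t: haps[t] for t in self.targets}


def gene_drop(
    pedigree: Pedigree, sim_map: SimMap, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One replicate; returns the proband's founder-label haplotype pair."""
    return GeneDropper(pedigree, sim_map).drop(rng)[pedigree.proband_id]


def assign_genotypes(
    label_pairs,
    sim_map: SimMap,
    rng: np.random.Generator,
    n_labels: int | None = None,
) -> np.ndarray:
    """Drop alleles onto founder haplotypes and read off genotypes.

    Each (founder label, marker) cell receives allele 1 with probability
    ``freq_a1[marker]``, independently across markers and labels, so HBD
    markers (shared label) are forcibly homozygous.  ``label_pairs`` is one
    ``(l1, l2)`` pair or a list of pairs sharing one founder-allele draw
    (consistent genotypes for e.g. sib pairs); returns an int8 genotype
    vector, or a matrix with one row per pair.
    """
    single = isinstance(label_pairs, tuple) and isinstance(label_pairs[0], np.ndarray)
    pairs = [label_pairs] if single else list(label_pairs)
    p = sim_map.markers.freq_a1
    if n_labels is None:
        n_labels = int(max(pair.max() for lp in pairs for pair in lp)) + 1
    # founder_allele[l, m] = True if haplotype label l carries allele 1 at m
    founder_a1 = rng.random((n_labels, len(sim_map))) < p
    cols = np.arange(len(sim_map))
    out = np.empty((len(pairs), len(sim_map)), dtype=np.int8)
    for i, (l1, l2) in enumerate(pairs):
        a = founder_a1[l1, cols]
        b = founder_a1[l2, cols]
        out[i] = np.where(a & b, HOM_A1, np.where(a | b, HET, HOM_A2))
    return out[0] if single else out


def simulate_replicates(
    degree: int,
    n_replicates: int,
    sim_map: SimMap,
    seed: int | np.random.SeedSequence = 0,
    genotypes: bool = True,
):
    """Yield ``(replicate_seed, genotype_vector | None, HBDTrack)`` tuples.

    Replicates are independent via spawned RNG streams; each replicate's
    spawn key is yielded so any single replicate can be regenerated.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates >= 1 required")
    ped = build_cousin_pedigree(degree)
    dropper = GeneDropper(ped, sim_map)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for i, child in enumerate(ss.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        labels = dropper.drop(rng)[ped.proband_id]
        track = hbd_track(labels)
        geno = None
        if genotypes:
            geno = assign_genotypes(labels, sim_map, rng, dropper.n_founder_haplotypes)
        yield i, geno, track


def replicates_to_dataset(sim_map: SimMap, genotype_rows: list[np.ndarray]) -> GenotypeDataset:
    """Pack per-replicate genotype vectors into a GenotypeDataset (one
    'individual' per replicate), e.g. for PED/MAP export."""
    ids = [f"rep{i + 1}" for i in range(len(genotype_rows))]
    return GenotypeDataset(ids, sim_map.markers, np.vstack(genotype_rows))
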