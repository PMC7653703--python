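"""Reference genome model: autosome lengths, centromeres, and probe maps.

Analyses operate on the 22 human autosomes only; sex chromosomes are
excluded throughout because tumor/reference hybridizations are sex-matched
and X/Y dosage is not interpretable as somatic copy number here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeSpec", "ProbeMap", "hg19_autosomes", "generate_probe_map"]

# hg19 autosome lengths (bp) and approximate centromere midpoints (bp),
# rounded to the cytoband resolution used for arm assignment.
_HG19_LENGTHS = {
    1: 249_250_621, 2: 243_199_373, 3: 198_022_430, 4: 191_154_276,
    5: 180_915_260, 6: 171_115_067, 7: 159_138_663, 8: 146_364_022,
    9: 141_213_431, 10: 135_534_747, 11: 135_006_516, 12: 133_851_895,
    13: 115_169_878, 14: 107_349_540, 15: 102_531_392, 16: 90_354_753,
    17: 81_195_210, 18: 78_077_248, 19: 59_128_983, 20: 63_025_520,
    21: 48_129_895, 22: 51_304_566,
}
_HG19_CENTROMERES = {
    1: 125_000_000, 2: 93_300_000, 3: 91_000_000, 4: 50_400_000,
    5: 48_400_000, 6: 61_000_000, 7: 59_900_000, 8: 45_600_000,
    9: 49_000_000, 10: 40_200_000, 11: 53_700_000, 12: 35_800_000,
    13: 17_900_000, 14: 17_600_000, 15: 19_000_000, 16: 36_600_000,
    17: 24_000_000, 18: 17_200_000, 19: 26_500_000, 20: 27_500_000,
    21: 13_200_000, 22: 14_700_000,
}


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its declared invariants."""


@dataclass(frozen=True)
class GenomeSpec:
    """Autosomal genome: chromosome lengths and centromere (arm boundary) positions.

    Parameters
    ----------
    lengths
        Mapping chromosome (1..22) -> length in bp.
    centromeres
        Mapping chromosome -> centromere position in bp; positions strictly
        inside the chromosome. Probes at position <= centromere are on the
        p arm, otherwise on the q arm.
    """

    lengths: dict[int, int] = field(default_factory=lambda: dict(_HG19_LENGTHS))
    centromeres: dict[int, int] = field(default_factory=lambda: dict(_HG19_CENTROMERES))

    def __post_init__(self) -> None:
        chroms = sorted(self.lengths)
        if chroms != sorted(self.centromeres):
            raise InvalidConfigError("lengths and centromeres cover different chromosomes")
        if len(chroms) != 22:
            raise InvalidConfigError(f"expected 22 autosomes, got {len(chroms)}")
        for c in chroms:
            if self.lengths[c] <= 0:
                raise InvalidConfigError(f"chromosome {c} has non-positive length")
            if not 0 < self.centromeres[c] < self.lengths[c]:
                raise InvalidConfigError(f"centromere of chromosome {c} outside chromosome")

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def arm_of(self, chrom: int, pos: int) -> str:
        return "p" if pos <= self.centromeres[chrom] else "q"


def hg19_autosomes() -> GenomeSpec:
    """The default genome: hg19 autosomes 1-22."""
    return GenomeSpec()


@dataclass(frozen=True)
class ProbeMap:
    """Ordered genomic probe coordinates with CGH/SNP class.

    ``table`` has columns ``probe_id`` (unique str), ``chrom`` (int 1..22),
    ``pos`` (1-based bp) and ``probe_class`` ("CGH" or "SNP"), sorted by
    (chrom, pos). Copy-number signal is read from all probes; the
    homozygosity channel exists only on SNP probes.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "chrom", "pos", "probe_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise InvalidConfigError(f"probe map missing columns: {sorted(missing)}")
        t = self.table
        if t["probe_id"].duplicated().any():
            raise InvalidConfigError("duplicate probe ids")
        key = t["chrom"].to_numpy() * 2**33 + t["pos"].to_numpy()
        if not np.all(np.diff(key) >= 0):
            raise InvalidConfigError("probe map not sorted by (chrom, pos)")
        if not t["probe_class"].isin(["CGH", "SNP"]).all():
            raise InvalidConfigError("probe_class must be CGH or SNP")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    @property
    def is_snp(self) -> np.ndarray:
        return (self.table["probe_class"] == "SNP").to_numpy()

    def chrom_slices(self) -> dict[int, slice]:
        """Contiguous index slice of each chromosome (map is sorted)."""
        out: dict[int, slice] = {}
        chrom = self.chrom
        boundaries = np.flatnonzero(np.diff(chrom) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(chrom)]])
        for s, e in zip(starts, ends):
            out[int(chrom[s])] = slice(int(s), int(e))
        return out

    def probe_indices_in(self, chrom: int, start: int, end: int) -> np.ndarray:
        """Indices of probes with start <= pos <= end on ``chrom``."""
        sl = self.chrom_slices().get(chrom)
        if sl is None:
            return np.array([], dtype=int)
        pos = self.pos[sl]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        return np.arange(sl.start + lo, sl.start + hi)


def generate_probe_map(
    genome: GenomeSpec,
    n_probes: int,
    snp_fraction: float = 0.0,
    seed: int = 0,
) -> ProbeMap:
    """Lay ``n_probes`` across the genome proportionally to chromosome length.

    Probe counts per chromosome follow a largest-remainder apportionment of
    the length shares (every chromosome receives at least one probe);
    positions are evenly spaced along each chromosome, mimicking the
    near-uniform backbone of a catalog CGH+SNP design. A ``snp_fraction``
    of probes, chosen uniformly at random, carries the SNP (homozygosity)
    channel in addition to copy-number signal.
    """
    if n_probes < len(genome.chromosomes):
        raise InvalidConfigError(
            f"n_probes={n_probes} is fewer than {len(genome.chromosomes)} chromosomes"
        )
    if not 0 <= snp_fraction < 1:
        raise InvalidConfigError("snp_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    chroms = genome.chromosomes
    lengths = np.array([genome.lengths[c] for c in chroms], dtype=float)
    shares = lengths / lengths.sum() * n_probes
    counts = np.maximum(np.floor(shares).astype(int), 1)
    # largest-remainder top-up to hit n_probes exactly
    deficit = n_probes - counts.sum()
    if deficit > 0:
        order = np.argsort(-(shares - np.floor(shares)))
        counts[order[:deficit]] += 1
    elif deficit < 0:
        order = np.argsort(shares - np.floor(shares))
        for i in order:
            if deficit == 0:
                break
            if counts[i] > 1:
                counts[i] -= 1
                deficit += 1

    rows = []
    for c, L, k in zip(chroms, lengths, counts):
        pos = np.linspace(1, L, int(k)).round().astype(np.int64)
        rows.append(pd.DataFrame({"chrom": c, "pos": pos}))
    table = pd.concat(rows, ignore_index=True)
    table["probe_id"] = [
        f"P{c:02d}_{p:09d}" for c, p in zip(table["chrom"], table["pos"])
    ]
    n_snp = int(round(snp_fraction * len(table)))
    cls = np.full(len(table), "CGH", dtype=object)
    if n_snp:
        cls[rng.choice(len(table), size=n_snp, replace=False)] = "SNP"
    table["probe_class"] = cls
    return ProbeMap(table[["probe_id", "chrom", "pos", "probe_class"]])
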