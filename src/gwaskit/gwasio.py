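"""Readers/writers for the standard pipeline formats and variant/sample-level QC.

All interval arithmetic is 0-based half-open internally; VCF positions are
1-based and converted on I/O. Dosages are expected alternate-allele counts in
[0, 2]; a boolean mask marks missing entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantRecord",
    "DosageMatrix",
    "AnnotationTrack",
    "RecombinationMap",
    "ASSOC_COLUMNS",
    "read_dosage_vcf",
    "write_dosage_vcf",
    "read_bed",
    "write_bed",
    "read_recomb_map",
    "write_recomb_map",
    "read_assoc_table",
    "write_assoc_table",
    "filter_variants",
    "filter_hardcall",
    "hwe_exact_test",
]


class VcfFormatError(ValueError):
    """Raised for malformed VCF input, annotated with the offending line."""


@dataclass(frozen=True)
class VariantRecord:
    """Per-variant metadata.

    Attributes
    ----------
    id : str
        Variant identifier (e.g. rs number or synthetic name).
    chrom : str
        Chromosome label.
    pos : int
        1-based position, as in VCF.
    ref, alt : str
        Reference and alternate alleles (non-empty).
    af : float
        Alternate-allele frequency in [0, 1].
    info : float
        Imputation info score in [0, 1] (1.0 for genotyped variants).
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    af: float = float("nan")
    info: float = 1.0

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if np.isfinite(self.af) and not 0.0 <= self.af <= 1.0:
            raise ValueError(f"allele frequency {self.af} outside [0, 1]")


@dataclass
class DosageMatrix:
    """Samples x variants matrix of expected alternate-allele dosages.

    ``dosages`` has shape (n_samples, n_variants) with values in [0, 2];
    entries flagged in ``missing`` are ignored by downstream computations.
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = len(self.samples), len(self.variants)
        if self.dosages.shape != (n, m):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{n} samples x {m} variants"
            )
        if self.missing is None:
            self.missing = np.zeros((n, m), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (n, m):
                raise ValueError("missingness mask shape mismatch")
        observed = self.dosages[~self.missing]
        if observed.size and (observed.min() < -1e-9 or observed.max() > 2 + 1e-9):
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def allele_frequencies(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Realized alternate-allele frequencies from observed dosages."""
        d = np.ma.array(self.dosages, mask=self.missing)
        if sample_mask is not None:
            d = d[np.asarray(sample_mask)]
        return np.asarray(d.mean(axis=0) / 2.0)

    def subset_variants(self, index: np.ndarray) -> "DosageMatrix":
        index = np.asarray(index)
        return DosageMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in index],
            dosages=self.dosages[:, index],
            missing=self.missing[:, index],
        )

    def subset_samples(self, index: np.ndarray) -> "DosageMatrix":
        index = np.asarray(index)
        return DosageMatrix(
            samples=[self.samples[i] for i in index],
            variants=list(self.variants),
            dosages=self.dosages[index],
            missing=self.missing[index],
        )


class AnnotationTrack:
    """Sorted, strand-agnostic, non-overlapping genomic interval set.

    Intervals are 0-based half-open. Overlapping or book-ended input
    intervals are merged on construction; labels of merged intervals are
    joined with commas.
    """

    def __init__(self, intervals, labels=None, merge_bookended: bool = False):
        rows = [(str(c), int(s), int(e)) for c, s, e in intervals]
        for c, s, e in rows:
            if s >= e:
                raise ValueError(f"empty or inverted interval {c}:{s}-{e}")
            if s < 0:
                raise ValueError(f"negative interval start {c}:{s}")
        if labels is None:
            labels = [""] * len(rows)
        if len(labels) != len(rows):
            raise ValueError("labels length mismatch")
        order = sorted(range(len(rows)), key=lambda i: (rows[i][0], rows[i][1], rows[i][2]))
        merged: list[list] = []
        for i in order:
            c, s, e = rows[i]
            lab = labels[i]
            if merged and merged[-1][0] == c and (
                s < merged[-1][2] or (merge_bookended and s == merged[-1][2])
            ):
                merged[-1][2] = max(merged[-1][2], e)
                if lab and lab != merged[-1][3]:
                    merged[-1][3] = f"{merged[-1][3]},{lab}" if merged[-1][3] else lab
            else:
                merged.append([c, s, e, lab])
        self._chroms = [m[0] for m in merged]
        self._starts = np.array([m[1] for m in merged], dtype=np.int64)
        self._ends = np.array([m[2] for m in merged], dtype=np.int64)
        self._labels = [m[3] for m in merged]
        # per-chromosome index for fast point queries
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in dict.fromkeys(self._chroms):
            sel = [i for i, c in enumerate(self._chroms) if c == chrom]
            self._by_chrom[chrom] = (self._starts[sel], self._ends[sel])

    def __len__(self) -> int:
        return len(self._chroms)

    def __iter__(self):
        return iter(zip(self._chroms, self._starts.tolist(), self._ends.tolist()))

    def __eq__(self, other):
        if not isinstance(other, AnnotationTrack):
            return NotImplemented
        return list(self) == list(other)

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        return list(self)

    @property
    def labels(self) -> list[str]:
        return list(self._labels)

    def chromosomes(self) -> set[str]:
        return set(self._chroms)

    def total_bp(self) -> int:
        return int((self._ends - self._starts).sum())

    def contains(self, chrom, positions) -> np.ndarray:
        """Membership of 0-based point positions in the half-open intervals."""
        positions = np.asarray(positions, dtype=np.int64)
        scalar = positions.ndim == 0
        positions = np.atleast_1d(positions)
        out = np.zeros(positions.shape, dtype=bool)
        if chrom in self._by_chrom:
            starts, ends = self._by_chrom[chrom]
            idx = np.searchsorted(starts, positions, side="right") - 1
            valid = idx >= 0
            out[valid] = positions[valid] < ends[idx[valid]]
        return bool(out[0]) if scalar else out

    def distance_to_nearest(self, chrom: str, start: int, end: int) -> float:
        """Gap (bp) between [start, end) and the nearest interval on chrom.

        Overlapping or book-ended intervals are at distance 0. Returns inf
        when the chromosome has no intervals.
        """
        if chrom not in self._by_chrom:
            return float("inf")
        starts, ends = self._by_chrom[chrom]
        left_gap = start - ends  # positive where interval entirely left of region
        right_gap = starts - end
        gaps = np.maximum(np.maximum(left_gap, right_gap), 0)
        return float(gaps.min())

    def union(self, other: "AnnotationTrack") -> "AnnotationTrack":
        return AnnotationTrack(
            list(self) + list(other), self._labels + other._labels
        )


@dataclass
class RecombinationMap:
    """Piecewise-linear cumulative genetic map on one chromosome.

    ``positions`` (bp) and ``cumulative_cm`` are non-decreasing and aligned;
    queries interpolate linearly between map points.
    """

    positions: np.ndarray
    rates: np.ndarray  # cM/Mb
    cumulative_cm: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        self.cumulative_cm = np.asarray(self.cumulative_cm, dtype=float)
        if not (len(self.positions) == len(self.rates) == len(self.cumulative_cm)):
            raise ValueError("map columns have unequal lengths")
        if len(self.positions) < 2:
            raise ValueError("map needs at least two points")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cumulative_cm) < 0):
            raise ValueError("cumulative cM must be non-decreasing")

    @classmethod
    def flat(cls, length_bp: int, rate_cm_per_mb: float = 1.0) -> "RecombinationMap":
        pos = np.array([0, length_bp], dtype=np.int64)
        cm = pos / 1e6 * rate_cm_per_mb
        return cls(pos, np.full(2, rate_cm_per_mb), cm)

    def covers(self, position: float) -> bool:
        return self.positions[0] <= position <= self.positions[-1]

    def cm_at(self, position) -> np.ndarray | float:
        return np.interp(position, self.positions, self.cumulative_cm)

    def bp_at(self, cm) -> np.ndarray | float:
        return np.interp(cm, self.cumulative_cm, self.positions)


ASSOC_COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "freq", "info", "beta", "se", "z", "p",
]


# ---------------------------------------------------------------------------
# VCF dosage I/O


def write_dosage_vcf(matrix: DosageMatrix, path) -> None:
    """Write a DosageMatrix as VCF 4.2 with FORMAT GT:DS.

    GT carries the rounded hard call, DS the dosage to 3 decimals; missing
    entries become ``./.:.``. AF and IMPINFO INFO fields carry the variant
    metadata.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">\n')
        fh.write('##INFO=<ID=IMPINFO,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.samples) + "\n")
        gt_codes = ("0/0", "0/1", "1/1")
        for j, v in enumerate(matrix.variants):
            af = matrix.allele_frequencies()[j] if not np.isfinite(v.af) else v.af
            info_field = f"AF={af:.6g};IMPINFO={v.info:.6g}"
            cells = []
            for i in range(matrix.n_samples):
                if matrix.missing[i, j]:
                    cells.append("./.:.")
                else:
                    d = matrix.dosages[i, j]
                    g = int(np.floor(d + 0.5))
                    cells.append(f"{gt_codes[g]}:{d:.3f}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"{info_field}\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def read_dosage_vcf(path) -> DosageMatrix:
    """Read a VCF with per-sample dosages (FORMAT/DS).

    Records lacking DS fall back to hard genotype calls from GT. Mixed
    ploidy is rejected; malformed records are reported with their data-line
    index.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    i = -1
    try:
        for i, rec in enumerate(vcf):
            if len(rec.ALT) != 1:
                raise VcfFormatError(
                    f"record {i} ({rec.CHROM}:{rec.POS}): expected exactly one ALT allele"
                )
            ploidies = {len(g) - 1 for g in rec.genotypes}  # last entry is phase flag
            if len(ploidies) > 1:
                raise VcfFormatError(
                    f"record {i} ({rec.CHROM}:{rec.POS}): mixed ploidy"
                )
            try:
                ds = rec.format("DS")
            except KeyError:
                ds = None
            if ds is not None:
                col = np.asarray(ds, dtype=float).reshape(-1)
                miss = ~np.isfinite(col) | (col < -1) | (col > 3)
                col = np.where(miss, 0.0, col)
            else:
                gts = np.array([g[:-1] for g in rec.genotypes], dtype=float)
                miss = (gts < 0).any(axis=1)
                col = np.where(miss, 0.0, gts.clip(min=0).sum(axis=1))
            af = rec.INFO.get("AF")
            info = rec.INFO.get("IMPINFO")
            variants.append(
                VariantRecord(
                    id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=rec.ALT[0],
                    af=float(af) if af is not None else float("nan"),
                    info=float(info) if info is not None else 1.0,
                )
            )
            columns.append(np.clip(col, 0.0, 2.0))
            masks.append(np.asarray(miss, dtype=bool))
    except VcfFormatError:
        raise
    except Exception as exc:  # cyvcf2 parse failures
        raise VcfFormatError(f"malformed VCF record at data line {i + 2}: {exc}") from exc
    if not variants:
        return DosageMatrix(samples, [], np.zeros((len(samples), 0)))
    return DosageMatrix(
        samples=samples,
        variants=variants,
        dosages=np.column_stack(columns),
        missing=np.column_stack(masks),
    )


# ---------------------------------------------------------------------------
# BED / recombination map / association table I/O


def read_bed(path) -> AnnotationTrack:
    """Read a BED3+ file (0-based half-open) into a normalized track.

    Extra columns beyond the third are preserved as a comma-joined label.
    An empty file yields an empty track.
    """
    intervals, labels = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"BED line has fewer than 3 columns: {line!r}")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
            labels.append(",".join(parts[3:]) if len(parts) > 3 else "")
    return AnnotationTrack(intervals, labels)


def write_bed(track: AnnotationTrack, path) -> None:
    with open(path, "w") as fh:
        for (chrom, start, end), label in zip(track, track.labels):
            row = f"{chrom}\t{start}\t{end}"
            if label:
                row += f"\t{label}"
            fh.write(row + "\n")


def read_recomb_map(path) -> RecombinationMap:
    df = pd.read_csv(path, sep="\t")
    expected = ["position_bp", "rate_cM_per_Mb", "cM"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"recombination map must have columns {expected}")
    return RecombinationMap(
        df["position_bp"].to_numpy(),
        df["rate_cM_per_Mb"].to_numpy(),
        df["cM"].to_numpy(),
    )


def write_recomb_map(rmap: RecombinationMap, path) -> None:
    pd.DataFrame(
        {
            "position_bp": rmap.positions,
            "rate_cM_per_Mb": rmap.rates,
            "cM": rmap.cumulative_cm,
        }
    ).to_csv(path, sep="\t", index=False)


def read_assoc_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("snp", "p") if c not in df.columns]
    if missing:
        raise ValueError(f"association table lacks required columns: {missing}")
    return df


def write_assoc_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# QC filters


def filter_variants(
    matrix: DosageMatrix,
    info_min: float = 0.4,
    maf_min: float = 0.01,
    reference_samples: np.ndarray | None = None,
    extra_info: dict[str, np.ndarray] | None = None,
):
    """Variant-level imputation QC.

    A variant is retained when its info score exceeds ``info_min`` in at
    least one dataset (the matrix's own scores plus any arrays supplied in
    ``extra_info``) AND its minor allele frequency exceeds ``maf_min`` in the
    reference sample subset (e.g. controls or non-transmitting parents).

    Returns (filtered matrix, exclusion report) where the report lists one
    row per excluded variant with the failing rule ("info" or "maf").
    """
    if reference_samples is None:
        ref_mask = np.ones(matrix.n_samples, dtype=bool)
    else:
        ref_mask = np.asarray(reference_samples, dtype=bool)
    if ref_mask.sum() == 0:
        raise ValueError("reference sample subset for the MAF filter is empty")

    info_sets = [np.array([v.info for v in matrix.variants], dtype=float)]
    for arr in (extra_info or {}).values():
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (matrix.n_variants,):
            raise ValueError("extra info array length mismatch")
        info_sets.append(arr)
    info_ok = np.any(np.stack(info_sets) > info_min, axis=0)

    freq = matrix.allele_frequencies(ref_mask)
    maf = np.minimum(freq, 1.0 - freq)
    maf_ok = maf > maf_min

    keep = info_ok & maf_ok
    reasons = []
    for j in np.flatnonzero(~keep):
        reason = "info" if not info_ok[j] else "maf"
        reasons.append(
            {"snp": matrix.variants[j].id, "reason": reason,
             "info": max(s[j] for s in info_sets), "maf": maf[j]}
        )
    report = pd.DataFrame(reasons, columns=["snp", "reason", "info", "maf"])
    return matrix.subset_variants(np.flatnonzero(keep)), report


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test P-value from genotype counts.

    Mid-P is not used; the returned P is the standard exact P summing
    heterozygote configurations no more probable than the observed one.
    """
    n_het, n_hom1, n_hom2 = int(n_het), int(n_hom1), int(n_hom2)
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return float("nan")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # enumerate heterozygote counts with the same parity as n_rare
    het_values = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    if het_values.size == 0:
        return 1.0
    from scipy.special import gammaln

    hom_rare = (n_rare - het_values) // 2
    hom_common = n - het_values - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(het_values + 1.0)
        - gammaln(hom_rare + 1.0)
        - gammaln(hom_common + 1.0)
        + het_values * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[het_values == n_het]
    if observed.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, probs[probs <= observed[0] * (1 + 1e-12)].sum()))


def _hard_call(dosages: np.ndarray, call_threshold: float):
    """Round dosages to genotypes, masking low-confidence calls.

    Confidence is 1 - 2|d - round(d)|, a monotone surrogate for the
    genotype-probability triple when only the dosage is stored.
    """
    g = np.floor(dosages + 0.5).astype(np.int8)
    conf = np.clip(1.0 - 2.0 * np.abs(dosages - g), 0.0, 1.0)
    missing = conf < call_threshold
    return g, missing


def filter_hardcall(
    matrix: DosageMatrix,
    status: np.ndarray,
    call_threshold: float = 0.9,
    callrate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    diffmiss_p_min: float = 0.05,
):
    """Hard-call dosages and apply variant-level genotype QC.

    Per genotype, a hard call is assigned when the implied call confidence
    reaches ``call_threshold``, otherwise the genotype is missing. Variants
    are then dropped unless call rate >= ``callrate_min``, MAF >= ``maf_min``,
    the exact HWE P on controls >= ``hwe_p_min``, and the two-sided Fisher
    test of differential missingness between cases and controls is
    non-significant (P >= ``diffmiss_p_min``). Monomorphic-after-calling
    variants are flagged in the report.

    Returns (genotypes, missing, keep_mask, report).
    """
    status = np.asarray(status, dtype=int)
    if status.shape != (matrix.n_samples,):
        raise ValueError("status labels must align with samples")
    if set(np.unique(status)) - {0, 1}:
        raise ValueError("status must be 0 (control) / 1 (case)")
    genotypes, missing = _hard_call(matrix.dosages, call_threshold)
    missing |= matrix.missing
    controls = status == 0
    cases = status == 1

    n, m = genotypes.shape
    keep = np.ones(m, dtype=bool)
    rows = []
    for j in range(m):
        miss_j = missing[:, j]
        called = ~miss_j
        call_rate = called.mean()
        reasons = []
        if call_rate < callrate_min:
            reasons.append("callrate")
        g = genotypes[called, j]
        if g.size:
            p = g.mean() / 2.0
            maf = min(p, 1 - p)
        else:
            maf = 0.0
        if maf < maf_min:
            reasons.append("maf")
        if g.size and (g == g[0]).all():
            reasons.append("monomorphic")
        gc = genotypes[controls & called, j]
        hwe_p = hwe_exact_test((gc == 1).sum(), (gc == 2).sum(), (gc == 0).sum())
        if np.isfinite(hwe_p) and hwe_p < hwe_p_min:
            reasons.append("hwe")
        table = [
            [int((miss_j & cases).sum()), int((~miss_j & cases).sum())],
            [int((miss_j & controls).sum()), int((~miss_j & controls).sum())],
        ]
        _, diffmiss_p = stats.fisher_exact(table, alternative="two-sided")
        if diffmiss_p < diffmiss_p_min:
            reasons.append("diffmiss")
        if reasons:
            keep[j] = False
            rows.append(
                {"snp": matrix.variants[j].id, "reason": ";".join(reasons),
                 "call_rate": call_rate, "maf": maf, "hwe_p": hwe_p,
                 "diffmiss_p": diffmiss_p}
            )
    report = pd.DataFrame(
        rows, columns=["snp", "reason", "call_rate", "maf", "hwe_p", "diffmiss_p"]
    )
    return genotypes, missing, keep, report
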