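"""Cross-platform detection concordance over a cutoff ladder.

The analysis asks a deliberately simple question: given gene-level expression
tables from several technologies (short-read sequencing, long-read nanopore
sequencing, qPCR) measured on the same sample, which genes does each
technology call *detected* at a given expression cutoff, and how concordant
are those calls?

The building blocks are:

* :func:`detect` — threshold one table into a :class:`DetectionSet`;
* :func:`tanimoto` — the Tanimoto (Jaccard) set similarity
  ``T(a, b) = |A ∩ B| / (|A| + |B| − |A ∩ B|)``, with
  :func:`classify_similarity` mapping the value onto interpretation bands;
* :func:`venn_partition` — the exclusive k-way Venn regions (2^k − 1 of them);
* :func:`reliability_tiers` — per gene, the number of platforms detecting it
  (more platforms = more reliable call);
* :func:`platform_unique` / :func:`undetected` / :func:`coverage` — the
  single-technology calls (candidate false positives), the genes no
  technology sees, and the fraction of the declared gene universe recovered;
* :func:`sweep` — all of the above at every cutoff of a ladder, assembled
  into a :class:`ConcordanceReport`;
* :func:`replicate_concordance` — the same-platform, different-campaign
  comparison (batch reproducibility) as a per-cutoff Tanimoto profile.

Cutoffs are applied in each platform's native unit with no cross-platform
normalization, and the comparison against the cutoff is exact floating-point
(no epsilon): the cutoff itself is the only threshold in play.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .io_tables import ExpressionTable, GeneUniverse, ValidationError, round6

__all__ = [
    "COMPARATORS",
    "BAND_IDENTICAL",
    "BAND_WEAKER",
    "BAND_DIFFERENT",
    "DetectionSet",
    "SweepConfig",
    "VennPartition",
    "PairSimilarity",
    "CutoffResult",
    "ConcordanceReport",
    "detect",
    "tanimoto",
    "classify_similarity",
    "venn_partition",
    "reliability_tiers",
    "platform_unique",
    "undetected",
    "coverage",
    "sweep",
    "replicate_concordance",
    "provenance_labels",
]

COMPARATORS = ("strictly_greater", "greater_or_equal")

BAND_IDENTICAL = "identical"
BAND_WEAKER = "weaker"
BAND_DIFFERENT = "considerably_different"

DEFAULT_CUTOFFS = (0.0, 0.1, 1.0, 5.0, 10.0)


@dataclass(frozen=True)
class DetectionSet:
    """The genes one platform/sample/batch calls detected at one cutoff."""

    genes: frozenset[str]
    platform: str
    sample: str
    batch: str
    cutoff: float
    comparator: str = "strictly_greater"

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValidationError(f"cutoff must be >= 0, got {self.cutoff}")
        if self.comparator not in COMPARATORS:
            raise ValidationError(
                f"unknown comparator {self.comparator!r}; expected one of {COMPARATORS}"
            )

    @property
    def provenance(self) -> tuple[str, str, str]:
        return (self.platform, self.sample, self.batch)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SweepConfig:
    """Cutoff ladder and comparator semantics for a concordance sweep.

    The default ladder {0, 0.1, 1, 5, 10} spans the thresholds commonly
    recommended for calling a gene expressed.  The comparator defaults to
    ``strictly_greater`` (a value of exactly 0 is *not* a detection at cutoff
    0) but ``greater_or_equal`` is first-class, because both conventions are
    in circulation; the choice is recorded in every detection set's
    provenance.
    """

    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    comparator: str = "strictly_greater"

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ValidationError(
                f"unknown comparator {self.comparator!r}; expected one of {COMPARATORS}"
            )
        if len(self.cutoffs) == 0:
            raise ValidationError("cutoff ladder is empty")
        for c in self.cutoffs:
            if c < 0:
                raise ValidationError(f"cutoffs must be >= 0, got {c}")
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValidationError(f"cutoffs must be strictly increasing: {self.cutoffs}")


@dataclass(frozen=True)
class VennPartition:
    """Exclusive k-way region counts: every detected gene sits in exactly one
    of the 2^k − 1 non-empty platform subsets."""

    labels: tuple[str, ...]
    region_counts: Mapping[frozenset[str], int]
    union_size: int
    common_all: int

    def region(self, *labels: str) -> int:
        """Count of genes detected by exactly this subset of platforms."""
        return self.region_counts.get(frozenset(labels), 0)

    def to_dict(self) -> dict:
        regions = {}
        for subset, count in self.region_counts.items():
            key = "&".join(l for l in self.labels if l in subset)
            regions[key] = count
        return {
            "labels": list(self.labels),
            "regions": regions,
            "union_size": self.union_size,
            "common_all": self.common_all,
        }


@dataclass(frozen=True)
class PairSimilarity:
    """Tanimoto value between two detection sets with its interpretation band.

    ``degenerate`` marks the empty-vs-empty convention (T := 1): two
    platforms that both detect nothing agree perfectly, but the value carries
    no evidence and is flagged as conventional.
    """

    a: str
    b: str
    value: float
    band: str
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "value": round6(self.value),
            "band": self.band,
            "degenerate": self.degenerate,
        }


def detect(
    table: ExpressionTable,
    cutoff: float,
    comparator: str = "strictly_greater",
    universe: GeneUniverse | None = None,
) -> DetectionSet:
    """Call the genes whose expression passes the cutoff on one table.

    A gene absent from the table counts as measured at zero.  When a universe
    is given, the call set is restricted to it (genes outside the declared
    universe are ignored, and universe genes missing from the table are
    implicit zeros).
    """
    if cutoff < 0:
        raise ValidationError(f"cutoff must be >= 0, got {cutoff}")
    if comparator == "strictly_greater":
        passes = lambda v: v > cutoff
    elif comparator == "greater_or_equal":
        passes = lambda v: v >= cutoff
    else:
        raise ValidationError(
            f"unknown comparator {comparator!r}; expected one of {COMPARATORS}"
        )
    if universe is None:
        genes = frozenset(g for g, v in table.values.items() if passes(v))
    else:
        genes = frozenset(
            g for g in universe.genes if passes(table.values.get(g, 0.0))
        )
    return DetectionSet(
        genes=genes,
        platform=table.platform,
        sample=table.sample,
        batch=table.batch,
        cutoff=cutoff,
        comparator=comparator,
    )


def _genes(s: DetectionSet | frozenset[str] | set[str]) -> frozenset[str]:
    if isinstance(s, DetectionSet):
        return s.genes
    return frozenset(s)


def tanimoto(a: DetectionSet | set[str] | frozenset[str],
             b: DetectionSet | set[str] | frozenset[str]) -> float:
    """Tanimoto set similarity |A ∩ B| / (|A| + |B| − |A ∩ B|).

    For binary membership this coincides with the Jaccard index.  Both sets
    empty returns 1.0 by convention (never a division by zero); report
    assembly flags that case as degenerate.
    """
    sa, sb = _genes(a), _genes(b)
    if not sa and not sb:
        return 1.0
    inter = len(sa & sb)
    return inter / (len(sa) + len(sb) - inter)


def classify_similarity(t: float) -> str:
    """Map a Tanimoto value onto its interpretation band.

    ``[0.7, 1.0]`` → identical; ``(0.55, 0.7)`` → weaker similarity;
    ``[0, 0.55]`` → considerably different.  The band edges honor the rule
    that 0.55 and below means the sets differ considerably, with half-open
    intervals resolving the overlap between the conventional ranges.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"Tanimoto value outside [0, 1]: {t}")
    if t >= 0.7:
        return BAND_IDENTICAL
    if t > 0.55:
        return BAND_WEAKER
    return BAND_DIFFERENT


def provenance_labels(sets: Sequence[DetectionSet]) -> tuple[str, ...]:
    """Shortest distinguishing labels for a collection of detection sets.

    Uses the platform tag alone when platforms are unique, otherwise
    platform:batch, otherwise the full platform:sample:batch triple.
    Duplicate (platform, sample, batch) provenance is an error.
    """
    prov = [s.provenance for s in sets]
    if len(set(prov)) != len(prov):
        raise ValidationError(f"duplicate provenance among detection sets: {prov}")
    for fields in ((0,), (0, 2), (0, 1, 2)):
        labels = tuple(":".join(p[i] for i in fields) for p in prov)
        if len(set(labels)) == len(labels):
            return labels
    raise AssertionError("unreachable")  # pragma: no cover


def _check_family(sets: Sequence[DetectionSet]) -> tuple[str, ...]:
    if len(sets) < 2:
        raise ValidationError("need at least two detection sets")
    return provenance_labels(sets)


def venn_partition(sets: Sequence[DetectionSet]) -> VennPartition:
    """Partition the union of 2–4 detection sets into exclusive Venn regions."""
    if not 2 <= len(sets) <= 4:
        raise ValidationError(f"venn_partition takes 2-4 sets, got {len(sets)}")
    labels = _check_family(sets)
    by_label = {lab: s.genes for lab, s in zip(labels, sets)}
    union: set[str] = set().union(*by_label.values())

    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(labels) + 1):
        for subset in combinations(labels, r):
            counts[frozenset(subset)] = 0
    for gene in union:
        members = frozenset(lab for lab in labels if gene in by_label[lab])
        counts[members] += 1

    return VennPartition(
        labels=labels,
        region_counts=counts,
        union_size=len(union),
        common_all=counts[frozenset(labels)],
    )


def reliability_tiers(sets: Sequence[DetectionSet]) -> dict[str, int]:
    """Per gene, the number of platforms detecting it (its reliability tier).

    The guiding rule: the more technologies a transcript is seen by, the more
    reliable its detection.  Genes detected by no set are absent from the
    mapping.
    """
    _check_family(sets)
    tiers: dict[str, int] = {}
    for s in sets:
        for gene in s.genes:
            tiers[gene] = tiers.get(gene, 0) + 1
    return tiers


def platform_unique(sets: Sequence[DetectionSet]) -> dict[str, list[str]]:
    """Genes detected by exactly one platform, keyed by that platform's label.

    These single-technology calls are the candidate false positives of the
    analysis; they equal the singleton regions of the Venn partition.
    """
    labels = _check_family(sets)
    tiers = reliability_tiers(sets)
    out: dict[str, list[str]] = {}
    for lab, s in zip(labels, sets):
        out[lab] = sorted(g for g in s.genes if tiers[g] == 1)
    return out


def undetected(sets: Sequence[DetectionSet], universe: GeneUniverse) -> list[str]:
    """Universe genes seen by no technology, in universe order."""
    union: set[str] = set().union(*(s.genes for s in sets)) if sets else set()
    return [g for g in universe.genes if g not in union]


def coverage(sets: Sequence[DetectionSet], universe: GeneUniverse) -> float:
    """Fraction of the declared gene universe detected by at least one set."""
    if universe.size == 0:  # unreachable: GeneUniverse forbids empty
        raise ValueError("empty gene universe")
    union: set[str] = set().union(*(s.genes for s in sets)) if sets else set()
    return len(union & set(universe.genes)) / universe.size


@dataclass(frozen=True)
class CutoffResult:
    """Everything the analysis computes at a single cutoff."""

    cutoff: float
    venn: VennPartition
    tanimoto: tuple[PairSimilarity, ...]
    tiers: Mapping[str, int]
    tier_counts: Mapping[int, int]
    unique: Mapping[str, tuple[str, ...]]
    undetected: tuple[str, ...]
    coverage: float

    def to_dict(self) -> dict:
        return {
            "cutoff": round6(self.cutoff),
            "venn": self.venn.to_dict(),
            "tanimoto": [t.to_dict() for t in self.tanimoto],
            "tier_counts": {str(k): v for k, v in sorted(self.tier_counts.items())},
            "unique": {lab: list(genes) for lab, genes in self.unique.items()},
            "undetected": list(self.undetected),
            "coverage": round6(self.coverage),
        }


@dataclass(frozen=True)
class ConcordanceReport:
    """Full per-cutoff concordance analysis of >= 2 expression tables."""

    universe_label: str
    universe_size: int
    labels: tuple[str, ...]
    inputs: tuple[dict, ...]
    comparator: str
    cutoffs: tuple[float, ...]
    results: tuple[CutoffResult, ...]

    def result_at(self, cutoff: float) -> CutoffResult:
        for res in self.results:
            if res.cutoff == cutoff:
                return res
        raise KeyError(f"cutoff {cutoff} not in report (have {self.cutoffs})")

    def to_dict(self) -> dict:
        return {
            "universe": {"label": self.universe_label, "size": self.universe_size},
            "labels": list(self.labels),
            "inputs": list(self.inputs),
            "comparator": self.comparator,
            "cutoffs": [round6(c) for c in self.cutoffs],
            "results": [r.to_dict() for r in self.results],
        }


def _pairwise_similarities(
    sets: Sequence[DetectionSet], labels: Sequence[str]
) -> tuple[PairSimilarity, ...]:
    out = []
    for (la, sa), (lb, sb) in combinations(zip(labels, sets), 2):
        degenerate = not sa.genes and not sb.genes
        t = tanimoto(sa, sb)
        out.append(
            PairSimilarity(a=la, b=lb, value=t, band=classify_similarity(t), degenerate=degenerate)
        )
    return tuple(out)


def sweep(
    tables: Sequence[ExpressionTable],
    universe: GeneUniverse,
    config: SweepConfig = SweepConfig(),
) -> ConcordanceReport:
    """Run the full concordance analysis at every cutoff of the ladder."""
    if len(tables) < 2:
        raise ValidationError("at least two tables required")
    prov = [t.provenance for t in tables]
    if len(set(prov)) != len(prov):
        raise ValidationError(f"duplicate provenance among input tables: {prov}")

    results = []
    labels: tuple[str, ...] | None = None
    for cutoff in config.cutoffs:
        sets = [detect(t, cutoff, config.comparator, universe) for t in tables]
        labels = provenance_labels(sets)
        venn = venn_partition(sets)
        tiers = reliability_tiers(sets)
        tier_counts = {
            k: sum(1 for v in tiers.values() if v == k) for k in range(1, len(sets) + 1)
        }
        unique = {
            lab: tuple(genes) for lab, genes in platform_unique(sets).items()
        }
        results.append(
            CutoffResult(
                cutoff=cutoff,
                venn=venn,
                tanimoto=_pairwise_similarities(sets, labels),
                tiers=tiers,
                tier_counts=tier_counts,
                unique=unique,
                undetected=tuple(undetected(sets, universe)),
                coverage=coverage(sets, universe),
            )
        )
    assert labels is not None
    inputs = tuple(
        {
            "label": lab,
            "platform": t.platform,
            "sample": t.sample,
            "batch": t.batch,
            "unit": t.unit,
            "n_genes": len(t),
        }
        for lab, t in zip(labels, tables)
    )
    return ConcordanceReport(
        universe_label=universe.label,
        universe_size=universe.size,
        labels=labels,
        inputs=inputs,
        comparator=config.comparator,
        cutoffs=tuple(config.cutoffs),
        results=tuple(results),
    )


def replicate_concordance(
    a: ExpressionTable,
    b: ExpressionTable,
    config: SweepConfig = SweepConfig(),
) -> list[PairSimilarity]:
    """Per-cutoff Tanimoto profile between two measurement campaigns.

    Both tables must come from the same platform and sample but different
    batches (e.g. the same cell line profiled years apart).  At cutoff 0 the
    comparison is scale-invariant: rescaling every value leaves the detection
    sets unchanged.
    """
    if a.platform != b.platform or a.sample != b.sample:
        raise ValidationError(
            "replicate comparison requires the same platform and sample: "
            f"{a.provenance} vs {b.provenance}"
        )
    if a.batch == b.batch:
        raise ValidationError(f"replicate comparison requires distinct batches: {a.batch!r}")
    out = []
    for cutoff in config.cutoffs:
        da = detect(a, cutoff, config.comparator)
        db = detect(b, cutoff, config.comparator)
        degenerate = not da.genes and not db.genes
        t = tanimoto(da, db)
        out.append(
            PairSimilarity(
                a=f"{a.platform}:{a.batch}",
                b=f"{b.platform}:{b.batch}",
                value=t,
                band=classify_similarity(t),
                degenerate=degenerate,
            )
        )
    return out
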