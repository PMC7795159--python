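"""IsomiR classification of small-RNA reads against a mature-miRNA reference.

Each read is anchored to a mature miRNA allowing bounded 5'/3' end shifts in
which every shifted or extended base must match the genomic template (mature
sequence plus flanks); any 3' suffix that cannot be templated is a candidate
non-templated tail.  Classes follow the sRNAbench-style nomenclature:

``canonical``
    exact mature match.
``nve``
    internal substitution(s) only, canonical ends.
``nta#A / nta#C / nta#G / nta#T``
    uniform-base non-templated 3' tail on otherwise canonical ends (the tail
    is reported in DNA alphabet, so an appended U becomes ``nta#T``).
``lv5p / lv3p``
    single-end templated length variant (trim, or extension matching the
    flank).
``mlv5p / mlv3p``
    both ends shifted; ``mlv5p`` when |offset5| >= |offset3| (ties go 5').
``mv``
    any other combination — tail plus shift, substitution plus shift, or a
    mixed-base tail.

Anchorings are scored lexicographically by (tail length, substitutions,
total end shift), i.e. templated explanations are always preferred over
non-templated ones; with several admissible parents the read is assigned to
the parent with the fewest modifications, ties broken by name.  Reads
shorter than 15 nt, or with no admissible anchoring, are no-calls — never
forced into ``mv``.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normfilter import CountMatrix

logger = logging.getLogger("tepomics.isomir")

CLASSES = (
    "canonical",
    "lv3p",
    "lv5p",
    "mlv3p",
    "mlv5p",
    "mv",
    "nve",
    "nta#A",
    "nta#C",
    "nta#G",
    "nta#T",
)

RNA_ALPHABET = frozenset("ACGU")
MIN_READ_LEN = 15

_RNA2DNA = str.maketrans("U", "T")


def to_dna(seq: str) -> str:
    return seq.translate(_RNA2DNA)


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class MatureMiRNA:
    """Reference mature miRNA with its genomic flanking sequence."""

    name: str
    mature_seq: str
    flank5: str
    flank3: str

    def __post_init__(self) -> None:
        for label, seq in (("mature_seq", self.mature_seq), ("flank5", self.flank5), ("flank3", self.flank3)):
            if not seq:
                raise ValueError(f"{self.name}: empty {label}")
            if not set(seq) <= RNA_ALPHABET:
                raise ValueError(f"{self.name}: {label} not over ACGU")
        if not 18 <= len(self.mature_seq) <= 26:
            raise ValueError(f"{self.name}: mature length {len(self.mature_seq)} outside 18-26")

    @property
    def extended(self) -> str:
        return self.flank5 + self.mature_seq + self.flank3


@dataclass(frozen=True)
class IsomiRCall:
    """One read's classification against its parent miRNA.

    ``offset5``/``offset3`` are signed shifts of the templated ends in the
    5'->3' direction: positive ``offset5`` trims the 5' end, positive
    ``offset3`` extends the 3' end into the flank.  ``tail`` is the
    non-templated 3' suffix in DNA alphabet.
    """

    read_seq: str
    parent: str
    class_label: str
    offset5: int
    offset3: int
    tail: str
    n_subs: int

    @property
    def feature_id(self) -> str:
        return f"{self.parent}|{self.class_label}|{self.offset5}|{self.offset3}|{self.tail}"


def _label(o5: int, o3: int, tail: str, n_subs: int) -> str:
    if o5 == 0 and o3 == 0 and not tail and n_subs == 0:
        return "canonical"
    if o5 == 0 and o3 == 0 and not tail and n_subs > 0:
        return "nve"
    if o5 == 0 and o3 == 0 and tail and n_subs == 0 and len(set(tail)) == 1:
        return f"nta#{to_dna(tail[0])}"
    if not tail and n_subs == 0:
        if o5 != 0 and o3 == 0:
            return "lv5p"
        if o3 != 0 and o5 == 0:
            return "lv3p"
        return "mlv5p" if abs(o5) >= abs(o3) else "mlv3p"
    return "mv"


def _best_anchoring(
    read: str,
    ref: MatureMiRNA,
    max_offset: int,
    max_tail: int,
    max_subs: int,
):
    """Minimum-cost anchoring of ``read`` to ``ref``, or None.

    Cost is (tail length, substitutions, |o5|+|o3|, o5, o3) compared
    lexicographically — deterministic and preferring templated explanations.
    """
    ext = ref.extended
    off0 = len(ref.flank5)
    mlen = len(ref.mature_seq)
    rlen = len(read)
    best = None
    for o5 in range(-min(max_offset, off0), max_offset + 1):
        start = off0 + o5
        for o3 in range(-max_offset, min(max_offset, len(ref.flank3)) + 1):
            end = off0 + mlen + o3
            core_len = end - start
            if core_len < MIN_READ_LEN or core_len > rlen:
                continue
            tail_len = rlen - core_len
            if tail_len > max_tail:
                continue
            core = ext[start:end]
            seg = read[:core_len]
            n_subs = 0
            bad = False
            for i in range(core_len):
                if seg[i] != core[i]:
                    # substitutions are only admissible strictly inside the
                    # mature body: core ends and flank-templated positions
                    # must match the template exactly
                    if i == 0 or i == core_len - 1 or not (off0 < start + i < off0 + mlen - 1):
                        bad = True
                        break
                    n_subs += 1
                    if n_subs > max_subs:
                        bad = True
                        break
            if bad:
                continue
            cost = (tail_len, n_subs, abs(o5) + abs(o3), o5, o3)
            if best is None or cost < best[0]:
                best = (cost, o5, o3, read[core_len:], n_subs)
    return best


def classify_read(
    read: str,
    ref: MatureMiRNA,
    max_offset: int = 3,
    max_tail: int = 3,
    max_subs: int = 1,
) -> IsomiRCall | None:
    """Classify one read against one reference entry (pure function)."""
    read = to_rna(read)
    if len(read) < MIN_READ_LEN:
        return None
    best = _best_anchoring(read, ref, max_offset, max_tail, max_subs)
    if best is None:
        return None
    _, o5, o3, tail, n_subs = best
    return IsomiRCall(
        read_seq=read,
        parent=ref.name,
        class_label=_label(o5, o3, tail, n_subs),
        offset5=o5,
        offset3=o3,
        tail=to_dna(tail),
        n_subs=n_subs,
    )


class ReferenceIndex:
    """K-mer prefilter so reads are only anchored against plausible parents.

    Indexes every 8-mer of each mature sequence; a read's candidate parents
    are the union over its own 8-mers.  For small references any read with
    no k-mer hit falls back to scanning all entries, so the index is purely
    an optimization, never a source of missed calls.
    """

    K = 8

    def __init__(
        self,
        reference: list[MatureMiRNA],
        max_offset: int = 3,
        max_tail: int = 3,
        max_subs: int = 1,
    ):
        names = [r.name for r in reference]
        if len(set(names)) != len(names):
            raise ValueError("duplicate names in reference")
        self.reference = sorted(reference, key=lambda r: r.name)
        self.max_offset = max_offset
        self.max_tail = max_tail
        self.max_subs = max_subs
        self._by_kmer: dict[str, set[str]] = defaultdict(set)
        self._by_name = {r.name: r for r in self.reference}
        for r in self.reference:
            s = r.mature_seq
            for i in range(len(s) - self.K + 1):
                self._by_kmer[s[i : i + self.K]].add(r.name)
        self._cache: dict[str, tuple[IsomiRCall | None, int]] = {}
        self.n_ambiguous = 0

    def _candidates(self, read: str) -> list[MatureMiRNA]:
        hits: set[str] = set()
        for i in range(len(read) - self.K + 1):
            hits |= self._by_kmer.get(read[i : i + self.K], set())
        if not hits:
            return self.reference
        return [self._by_name[n] for n in sorted(hits)]

    def classify(self, read: str) -> IsomiRCall | None:
        read = to_rna(read)
        cached = self._cache.get(read)
        if cached is not None:
            call, amb = cached
            self.n_ambiguous += amb
            return call
        if len(read) < MIN_READ_LEN:
            self._cache[read] = (None, 0)
            return None
        scored = []
        for ref in self._candidates(read):
            best = _best_anchoring(read, ref, self.max_offset, self.max_tail, self.max_subs)
            if best is not None:
                scored.append((best[0], ref.name, best))
        if not scored:
            self._cache[read] = (None, 0)
            return None
        amb = 1 if len(scored) > 1 else 0
        if amb:
            logger.debug("ambiguous read %s matches %d parents", read, len(scored))
        scored.sort()  # cost, then name (D6 tie-break)
        cost, name, (_, o5, o3, tail, n_subs) = scored[0]
        call = IsomiRCall(
            read_seq=read,
            parent=name,
            class_label=_label(o5, o3, tail, n_subs),
            offset5=o5,
            offset3=o3,
            tail=to_dna(tail),
            n_subs=n_subs,
        )
        self._cache[read] = (call, amb)
        self.n_ambiguous += amb
        return call


def count_isomirs(
    reads_by_sample: dict[str, list[str]],
    reference: list[MatureMiRNA],
    groups: pd.Series | dict,
    max_offset: int = 3,
    max_tail: int = 3,
    max_subs: int = 1,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Classify all reads and build canonical + isomiR count matrices.

    The canonical matrix aggregates every call (canonical and variants) per
    parent miRNA, matching the convention that canonical miRNA expression
    sums its reads.  IsomiR features are keyed
    ``parent|class|offset5|offset3|tail``.  No-calls are excluded from both
    matrices and tallied, per sample, in the QC report together with
    ambiguous-parent counts.
    """
    if not isinstance(groups, pd.Series):
        groups = pd.Series(groups)
    samples = list(reads_by_sample)
    if not any(reads_by_sample.values()):
        logger.warning("empty read set: returning empty matrices")
    index = ReferenceIndex(reference, max_offset, max_tail, max_subs)

    canonical: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    isomir: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    qc_rows = []
    for sample in samples:
        n_nocall = 0
        amb_before = index.n_ambiguous
        for read in reads_by_sample[sample]:
            call = index.classify(read)
            if call is None:
                n_nocall += 1
                continue
            canonical[call.parent][sample] += 1
            if call.class_label != "canonical":
                isomir[call.feature_id][sample] += 1
        qc_rows.append(
            {
                "sample": sample,
                "n_reads": len(reads_by_sample[sample]),
                "n_no_call": n_nocall,
                "n_ambiguous": index.n_ambiguous - amb_before,
            }
        )

    def build(table: dict, layer: str) -> CountMatrix:
        df = pd.DataFrame(
            {s: {f: table[f].get(s, 0) for f in table} for s in samples},
            dtype=np.int64,
        )
        if df.empty:
            df = pd.DataFrame(index=pd.Index([], dtype=object), columns=samples, dtype=np.int64)
        return CountMatrix(layer, df.sort_index(), groups)

    qc = pd.DataFrame(qc_rows).set_index("sample")
    return build(canonical, "mirna"), build(isomir, "isomir"), qc


def parent_of(feature_id: str) -> str:
    """Parent miRNA of an isomiR feature id (``parent|class|o5|o3|tail``)."""
    return feature_id.split("|")[0]


def class_of(feature_id: str) -> str:
    return feature_id.split("|")[1]


def class_frequency(
    isomir_matrix: CountMatrix,
    de_mirnas: list[str],
    prior_count: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group isomiR class profile restricted to DE canonical miRNAs.

    Frequencies are abundance-weighted: for each group, the CPM mass of each
    class among isomiR features of the DE miRNAs divided by the group's
    total.  The second table carries log2(mean CPM + prior) per
    (miRNA, class, group) — heatmap-style average expression.
    """
    if not de_mirnas:
        raise ValueError("de_mirnas must be non-empty")
    de_set = set(de_mirnas)
    feats = [f for f in isomir_matrix.features if parent_of(f) in de_set]
    from .normfilter import cpm as _cpm

    c = _cpm(isomir_matrix).loc[feats]
    freq = {}
    expr_rows = []
    for g in ("A", "B"):
        cols = isomir_matrix.samples_in_group(g)
        mean_cpm = c[cols].mean(axis=1)
        by_class = mean_cpm.groupby([class_of(f) for f in feats]).sum()
        total = by_class.sum()
        freq[g] = by_class / total if total > 0 else by_class
        by_mir_class = mean_cpm.groupby(
            [[parent_of(f) for f in feats], [class_of(f) for f in feats]]
        ).sum()
        for (mir, cls), v in by_mir_class.items():
            expr_rows.append(
                {"mirna": mir, "class": cls, "group": g, "log2_mean_cpm": float(np.log2(v + prior_count))}
            )
    classes = [c_ for c_ in CLASSES if c_ != "canonical"]
    freq_df = pd.DataFrame(freq).reindex(classes).fillna(0.0)
    freq_df.index.name = "class"
    return freq_df, pd.DataFrame(expr_rows)
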