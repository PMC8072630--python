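"""Fixed-length representations of read groups.

Four kinds feed the networks:

* ``kmer_count`` — counts of reference-derived k-mers (default k=16; k=31
  supported) matched in both read orientations, alignment-free;
* ``kmer_freq`` — the same counts normalized to sum to 1;
* ``coverage`` — per-base read depth over the concatenated scope exons
  (transcript order), computed from alignment match intervals;
* ``coverage_freq`` — coverage normalized to sum to 1.

The k-mer vocabulary is the ordered set of distinct k-mers sliding over
the wild-type spliced sequence of the scope, optionally augmented with the
novel k-mers spanning the skip junction (exon 13 - exon 15 by default), so
exon-14 skipping leaves *presence* evidence, not only absence.  Counting
only vocabulary k-mers fixes the input dimension.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, SchemaMismatchError
from .gene_model import GeneModel
from .subsampling import ReadGroup

logger = logging.getLogger(__name__)

DEFAULT_K = 16
SUPPORTED_KS = (16, 31)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i

FEATURE_KINDS = ("kmer_count", "kmer_freq", "coverage", "coverage_freq")
_FREQ_OF = {"kmer_count": "kmer_freq", "coverage": "coverage_freq"}


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-windows along the last axis + validity mask.

    Works on 1-D (single sequence) or 2-D (batch of equal-length reads)
    code arrays; windows containing a non-ACGT base are flagged invalid.
    """
    if codes.shape[-1] < k:
        empty_shape = codes.shape[:-1] + (0,)
        return np.zeros(empty_shape, dtype=np.uint64), np.zeros(empty_shape, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k, axis=-1)
    valid = (win != 255).all(axis=-1)
    weights = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    vals = (win.astype(np.uint64) * weights).sum(axis=-1)
    return vals, valid


@dataclass(frozen=True)
class FeatureVector:
    """One representation of one read group over a stated exon scope."""

    kind: str
    scope: tuple[int, ...]
    values: np.ndarray
    group_id: str
    k: int | None = None
    warning: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise DataError(f"unknown feature kind {self.kind!r}")
        if np.any(self.values < 0):
            raise DataError("feature values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


class KmerVocabulary:
    """Ordered distinct k-mers of a scope's spliced sequence (first-occurrence
    order), each attributed to the exon(s) its first occurrence overlaps.

    With ``include_skip_junction`` the k-mers unique to the skip junction
    (flanking exons of the configured skip exon spliced together) are
    appended; they are attributed to both flanking exons.
    """

    def __init__(
        self,
        gene_model: GeneModel,
        k: int = DEFAULT_K,
        scope: tuple[int, ...] | None = None,
        include_skip_junction: bool = True,
        skip_exon: int = 14,
    ) -> None:
        if k < 2:
            raise DataError("k must be >= 2")
        scope = tuple(scope) if scope else tuple(e.ordinal for e in gene_model.exons)
        if not scope:
            raise DataError("scope must be non-empty")
        seq = gene_model.spliced_sequence(scope)
        if len(seq) < k:
            raise DataError(f"scope sequence length {len(seq)} shorter than k={k}")

        # position -> exon ordinal along the spliced scope
        pos_exon = np.concatenate(
            [np.full(len(gene_model.exon(o)), o, dtype=np.int64) for o in scope]
        )
        self.k = k
        self.scope = scope
        self.skip_exon = skip_exon
        self.kmers: list[str] = []
        self.attribution: list[tuple[int, ...]] = []
        index: dict[str, int] = {}
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if km not in index:
                index[km] = len(self.kmers)
                self.kmers.append(km)
                self.attribution.append(tuple(sorted(set(pos_exon[i : i + k].tolist()))))

        if include_skip_junction and skip_exon in scope:
            ordinals = [e.ordinal for e in gene_model.exons]
            j = ordinals.index(skip_exon)
            if 0 < j < len(ordinals) - 1:
                left, right = ordinals[j - 1], ordinals[j + 1]
                ls, rs = gene_model.exon(left).sequence, gene_model.exon(right).sequence
                junction = ls[-(k - 1):] + rs[: k - 1]
                boundary = len(ls[-(k - 1):])
                for i in range(len(junction) - k + 1):
                    km = junction[i : i + k]
                    if km not in index:
                        index[km] = len(self.kmers)
                        self.kmers.append(km)
                        attrib = set()
                        if i < boundary:
                            attrib.add(left)
                        if i + k > boundary:
                            attrib.add(right)
                        self.attribution.append(tuple(sorted(attrib)))

        self.index = index
        stacked = _encode("".join(self.kmers)).reshape(len(self.kmers), k)
        codes, valid = _window_codes(stacked, k)
        if not valid.all():
            raise DataError("vocabulary contains non-ACGT bases")
        self.codes = codes[:, 0]
        self._order = np.argsort(self.codes, kind="stable")
        self._sorted_codes = self.codes[self._order]

    def __len__(self) -> int:
        return len(self.kmers)

    @property
    def hash(self) -> str:
        h = hashlib.sha256()
        h.update(f"k={self.k};scope={self.scope};".encode())
        h.update("".join(self.kmers).encode())
        return h.hexdigest()[:16]

    def lookup(self, window_codes: np.ndarray, valid: np.ndarray) -> np.ndarray:
        """Vocabulary indices of matching windows (invalid/missing dropped)."""
        flat, vmask = window_codes.ravel(), valid.ravel()
        pos = np.searchsorted(self._sorted_codes, flat)
        pos_c = np.minimum(pos, len(self._sorted_codes) - 1)
        hit = vmask & (pos < len(self._sorted_codes)) & (self._sorted_codes[pos_c] == flat)
        return self._order[pos_c[hit]]


def build_vocabulary(
    gene_model: GeneModel,
    k: int = DEFAULT_K,
    scope: tuple[int, ...] | None = None,
    include_skip_junction: bool = True,
    skip_exon: int = 14,
) -> KmerVocabulary:
    """Convenience constructor for :class:`KmerVocabulary`."""
    return KmerVocabulary(gene_model, k, scope, include_skip_junction, skip_exon)


def kmer_features(group: ReadGroup, vocab: KmerVocabulary) -> FeatureVector:
    """Count vocabulary k-mers across the group's reads, alignment-free.

    Every k-window of every read is tested in the read orientation and in
    the read's reverse complement; each match increments its vocabulary
    slot.  Non-vocabulary k-mers are ignored; reads shorter than k
    contribute nothing.
    """
    if not group.reads:
        raise DataError(f"group {group.group_id} has no reads")
    counts = np.zeros(len(vocab), dtype=np.float64)
    by_len: dict[int, list[str]] = {}
    short = 0
    for r in group.reads:
        if len(r.sequence) < vocab.k:
            short += 1
            continue
        by_len.setdefault(len(r.sequence), []).append(r.sequence)
    if short:
        logger.info("group %s: %d reads shorter than k=%d ignored", group.group_id, short, vocab.k)
    for L, seqs in by_len.items():
        batch = _encode("".join(seqs)).reshape(len(seqs), L)
        flipped = batch[:, ::-1]
        revcomp = np.where(flipped == 255, np.uint8(255), (3 - flipped).astype(np.uint8))
        for arr in (batch, revcomp):  # read orientation + reverse complement
            codes, valid = _window_codes(arr, vocab.k)
            idx = vocab.lookup(codes, valid)
            np.add.at(counts, idx, 1)
    return FeatureVector("kmer_count", vocab.scope, counts, group.group_id, k=vocab.k)


def to_frequency(fv: FeatureVector) -> FeatureVector:
    """Normalize a count/coverage vector to sum to 1 (all-zero passes
    through unchanged with the warning flag set)."""
    if fv.kind not in _FREQ_OF:
        raise DataError(f"cannot convert kind {fv.kind!r} to a frequency")
    total = fv.values.sum()
    if total == 0:
        logger.warning("group %s: all-zero %s vector", fv.group_id, fv.kind)
        return FeatureVector(_FREQ_OF[fv.kind], fv.scope, fv.values.copy(), fv.group_id, fv.k, True)
    return FeatureVector(
        _FREQ_OF[fv.kind], fv.scope, fv.values / total, fv.group_id, fv.k, fv.warning
    )


def _scope_layout(gene_model: GeneModel, scope: tuple[int, ...]):
    """(exon, block offset) pairs in transcript order + total length."""
    layout, off = [], 0
    for o in scope:
        e = gene_model.exon(o)
        layout.append((e, off))
        off += len(e)
    return layout, off


def coverage_features(
    group: ReadGroup, gene_model: GeneModel, scope: tuple[int, ...] = (13, 14, 15)
) -> FeatureVector:
    """Per-base depth over the concatenated scope exons, transcript order.

    A read increments every scope base covered by one of its alignment
    match blocks (soft-clipped bases excluded).  Groups with no aligned
    read yield an all-zero vector with the warning flag set.
    """
    scope = tuple(scope)
    layout, dim = _scope_layout(gene_model, scope)
    depth = np.zeros(dim, dtype=np.float64)
    any_aligned = False
    minus = gene_model.strand == "-"
    for r in group.reads:
        if not r.is_aligned:
            continue
        any_aligned = True
        for blk in r.blocks:
            for e, off in layout:
                iv = e.interval
                lo, hi = max(blk.start, iv.start), min(blk.end, iv.end)
                if lo >= hi:
                    continue
                if minus:
                    depth[off + (iv.end - hi) : off + (iv.end - lo)] += 1
                else:
                    depth[off + (lo - iv.start) : off + (hi - iv.start)] += 1
    warn = not any_aligned
    if warn:
        logger.warning("group %s: no aligned reads, zero coverage", group.group_id)
    return FeatureVector("coverage", scope, depth, group.group_id, warning=warn)


def exon_block_slices(gene_model: GeneModel, scope: tuple[int, ...]) -> dict[int, slice]:
    """Exon ordinal -> slice of its block inside the coverage vector."""
    layout, _ = _scope_layout(gene_model, tuple(scope))
    return {e.ordinal: slice(off, off + len(e)) for e, off in layout}


def feature_exon_attribution(
    kind: str,
    gene_model: GeneModel,
    scope: tuple[int, ...],
    vocab: KmerVocabulary | None = None,
) -> list[tuple[int, ...]]:
    """Exon ordinal(s) each feature belongs to — the wiring information the
    sparsely connected autoencoder mask is built from."""
    if kind.startswith("coverage"):
        layout, _ = _scope_layout(gene_model, tuple(scope))
        out: list[tuple[int, ...]] = []
        for e, _off in layout:
            out.extend([(e.ordinal,)] * len(e))
        return out
    if kind.startswith("kmer"):
        if vocab is None:
            raise DataError("k-mer attribution requires the vocabulary")
        return list(vocab.attribution)
    raise DataError(f"unknown feature kind {kind!r}")


# ---------------------------------------------------------------------------
# feature-matrix I/O (TSV + JSON schema sidecar)
# ---------------------------------------------------------------------------

def feature_schema(
    kind: str,
    scope: tuple[int, ...],
    n_features: int,
    k: int | None = None,
    vocabulary_hash: str | None = None,
) -> dict:
    return {
        "kind": kind,
        "scope": list(scope),
        "n_features": int(n_features),
        "k": k,
        "vocabulary_hash": vocabulary_hash,
    }


def schema_digest(schema: dict) -> str:
    return hashlib.sha256(json.dumps(schema, sort_keys=True).encode()).hexdigest()[:16]


def stack_features(fvs: list[FeatureVector]) -> tuple[list[str], np.ndarray]:
    if not fvs:
        raise DataError("no feature vectors to stack")
    dims = {len(fv) for fv in fvs}
    kinds = {fv.kind for fv in fvs}
    if len(dims) != 1 or len(kinds) != 1:
        raise DataError("feature vectors differ in dimension or kind")
    return [fv.group_id for fv in fvs], np.vstack([fv.values for fv in fvs])


def write_feature_matrix(
    fvs: list[FeatureVector],
    tsv_path: str | Path,
    schema: dict,
    labels: list[str] | None = None,
) -> None:
    """Rows = groups, columns = features; schema JSON sidecar next to it."""
    ids, X = stack_features(fvs)
    df = pd.DataFrame(X, index=pd.Index(ids, name="group_id"))
    df.columns = [f"f{i}" for i in range(X.shape[1])]
    if labels is not None:
        df.insert(0, "label", labels)
    df.to_csv(tsv_path, sep="\t", float_format="%.10g")
    Path(tsv_path).with_suffix(".schema.json").write_text(json.dumps(schema, indent=2))


def load_feature_matrix(tsv_path: str | Path):
    """Returns (group_ids, X, labels_or_None, schema); validates dimension
    against the sidecar schema."""
    df = pd.read_csv(tsv_path, sep="\t", index_col="group_id")
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").tolist()
    schema_path = Path(tsv_path).with_suffix(".schema.json")
    schema = json.loads(schema_path.read_text())
    X = df.to_numpy(dtype=np.float64)
    if X.shape[1] != schema["n_features"]:
        raise SchemaMismatchError(
            f"{tsv_path}: {X.shape[1]} columns but schema declares {schema['n_features']}"
        )
    return df.index.tolist(), X, labels, schema
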