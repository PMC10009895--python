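"""k-mer pseudoalignment and EM transcript-abundance estimation.

A read is assigned not to a position but to the set of transcripts
compatible with its k-mer content: the intersection of the transcript
sets of all its k-mers found in the index (k-mers absent from the index
are skipped, which tolerates isolated sequencing errors).  Reads are
aggregated into equivalence classes — sets of transcripts sharing
identical compatibility — and an EM algorithm distributes the ambiguous
classes over transcripts in proportion to abundance per unit effective
length.  Abundances are reported as TPM (transcripts per million), and
a transcript is called expressed when its TPM exceeds a threshold
(default 1).

k-mers are matched strand-insensitively through canonical codes:
each k-mer and its reverse complement are 2-bit encoded and the smaller
of the two integers represents both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .hla import TranscriptRecord

__all__ = [
    "KmerIndex",
    "EquivalenceClassCounts",
    "AbundanceTable",
    "ExpressionCall",
    "build_index",
    "pseudoalign",
    "em_abundances",
    "compute_tpm",
    "call_expressed",
    "fold_change",
    "quantify_reads",
    "utr_effect_experiment",
]

logger = logging.getLogger(__name__)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4


def _encode_seq(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({c for c in seq if _CODE[ord(c)] == 255})
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    return arr


def _canonical_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mer codes for each window of each row of ``mat``.

    ``mat`` is (n, L) with values 0-3 (A,C,G,T) or 4 (N).  Returns
    (n, L-k+1) int64 codes; windows containing N are set to -1.
    """
    n, L = mat.shape
    p = L - k + 1
    if p <= 0:
        return np.empty((n, 0), dtype=np.int64)
    valid = mat < 4
    b = np.where(valid, mat, 0).astype(np.int64)
    fwd = np.zeros((n, p), dtype=np.int64)
    rev = np.zeros((n, p), dtype=np.int64)
    for j in range(k):
        col = b[:, j : j + p]
        fwd += col * (4 ** (k - 1 - j))
        rev += (3 - col) * (4**j)
    canon = np.minimum(fwd, rev)
    # invalidate windows touching an N
    cs = np.zeros((n, L + 1), dtype=np.int32)
    np.cumsum(valid, axis=1, out=cs[:, 1:])
    ok = (cs[:, k:] - cs[:, :-k]) == k
    canon[~ok] = -1
    return canon


@dataclass
class KmerIndex:
    """k-mer -> transcript-set index plus per-transcript lengths.

    ``eff_lengths`` counts valid read start positions,
    ``max(1, length - read_length + 1)``; transcripts shorter than the
    read length are retained with an effective length floor of 1.
    """

    k: int
    read_length: int
    kmer_map: dict[int, frozenset[str]]
    lengths: dict[str, int]
    eff_lengths: dict[str, float]
    ids: list[str]
    allele_ids: frozenset[str] = frozenset()
    # fast-lookup arrays, parallel: sorted codes -> id into _sets
    _sorted_codes: np.ndarray = field(default=None, repr=False)
    _set_ids: np.ndarray = field(default=None, repr=False)
    _sets: list[frozenset[str]] = field(default=None, repr=False)


def build_index(
    transcripts: Sequence[TranscriptRecord], k: int = 21, read_length: int = 150
) -> KmerIndex:
    """Index every length-``k`` substring (canonical form) of every transcript."""
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError(f"k must be odd and in [11, 31], got {k}")
    ids = [t.id for t in transcripts]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids")
    lengths: dict[str, int] = {}
    eff_lengths: dict[str, float] = {}
    code_sets: dict[int, set[str]] = {}
    for t in transcripts:
        L = len(t.sequence)
        if L < k:
            raise ValueError(
                f"transcript {t.id} (length {L}) is shorter than k={k}"
            )
        lengths[t.id] = L
        eff_lengths[t.id] = float(max(1, L - read_length + 1))
        arr = _encode_seq(t.sequence)
        canon = _canonical_codes(arr[None, :], k)[0]
        for code in np.unique(canon):
            if code >= 0:
                code_sets.setdefault(int(code), set()).add(t.id)
    kmer_map = {c: frozenset(s) for c, s in code_sets.items()}
    # intern distinct transcript sets for array-based lookup
    interned: dict[frozenset[str], int] = {}
    sets: list[frozenset[str]] = []
    codes = np.fromiter(kmer_map.keys(), dtype=np.int64, count=len(kmer_map))
    set_ids = np.empty(len(kmer_map), dtype=np.int32)
    for i, code in enumerate(kmer_map):
        s = kmer_map[code]
        sid = interned.get(s)
        if sid is None:
            sid = len(sets)
            interned[s] = sid
            sets.append(s)
        set_ids[i] = sid
    order = np.argsort(codes)
    allele_ids = frozenset(t.id for t in transcripts if t.source == "hla_allele")
    return KmerIndex(
        k=k,
        read_length=read_length,
        kmer_map=kmer_map,
        lengths=lengths,
        eff_lengths=eff_lengths,
        ids=ids,
        allele_ids=allele_ids,
        _sorted_codes=codes[order],
        _set_ids=set_ids[order],
        _sets=sets,
    )


@dataclass
class EquivalenceClassCounts:
    """Read counts keyed by sorted transcript-id tuples."""

    counts: dict[tuple[str, ...], int] = field(default_factory=dict)
    unassigned: int = 0

    @property
    def total_assigned(self) -> int:
        return sum(self.counts.values())


def pseudoalign(
    reads: Iterable[str], index: KmerIndex, *, batch_size: int = 20000
) -> EquivalenceClassCounts:
    """Assign each read to its compatibility class.

    A read's class is the intersection of the transcript sets of all its
    k-mers present in the index; k-mers absent from the index are
    skipped.  Reads with no indexed k-mer, or an empty intersection, are
    unassigned.
    """
    k = index.k
    counts: dict[tuple[str, ...], int] = {}
    unassigned = 0
    pattern_cache: dict[bytes, Optional[tuple[str, ...]]] = {}
    by_length: dict[int, list[str]] = {}
    for r in reads:
        by_length.setdefault(len(r), []).append(r)
    for L, group in by_length.items():
        if L < k:
            unassigned += len(group)
            continue
        for start in range(0, len(group), batch_size):
            chunk = group[start : start + batch_size]
            mat = np.empty((len(chunk), L), dtype=np.uint8)
            for i, r in enumerate(chunk):
                mat[i] = _encode_seq(r)
            canon = _canonical_codes(mat, k)
            pos = np.searchsorted(index._sorted_codes, canon)
            pos_c = np.clip(pos, 0, len(index._sorted_codes) - 1)
            present = index._sorted_codes[pos_c] == canon
            sids = np.where(present, index._set_ids[pos_c], -1)
            for i in range(len(chunk)):
                row = sids[i]
                row = row[row >= 0]
                if row.size == 0:
                    unassigned += 1
                    continue
                uniq = np.unique(row)
                key = uniq.tobytes()
                ec = pattern_cache.get(key, False)
                if ec is False:
                    inter = frozenset.intersection(
                        *(index._sets[j] for j in uniq)
                    )
                    ec = tuple(sorted(inter)) if inter else None
                    pattern_cache[key] = ec
                if ec is None:
                    unassigned += 1
                else:
                    counts[ec] = counts.get(ec, 0) + 1
    return EquivalenceClassCounts(counts=counts, unassigned=unassigned)


@dataclass
class AbundanceTable:
    """Per-transcript estimated counts, effective lengths, and TPM."""

    df: pd.DataFrame  # index: transcript id; columns est_counts, eff_length, tpm
    condition: Optional[str] = None
    cell_line: Optional[str] = None
    converged: bool = True
    n_iter: int = 0
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def est_counts(self) -> pd.Series:
        return self.df["est_counts"]

    @property
    def tpm(self) -> pd.Series:
        return self.df["tpm"]

    def to_tsv(self, path: str | Path, calls: Optional[list["ExpressionCall"]] = None) -> None:
        out = self.df.copy()
        out.index.name = "transcript_id"
        if calls is not None:
            expressed = {c.transcript_id: c.expressed for c in calls}
            out["expressed"] = [expressed.get(t, False) for t in out.index]
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col="transcript_id")
        return cls(df=df[["est_counts", "eff_length", "tpm"]].astype(float))


def em_abundances(
    ecs: EquivalenceClassCounts,
    index: KmerIndex,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> AbundanceTable:
    """Distribute equivalence-class counts over transcripts by EM.

    Update: ``alpha_t <- sum_ec c_ec * (alpha_t/l_t) / sum_{t' in ec}
    (alpha_{t'}/l_{t'})`` from uniform initialization, where ``l`` is
    the effective length.  Total estimated counts equal the assigned
    read count after every iteration.  The multinomial log-likelihood is
    tracked per iteration in ``loglik_trace``.
    """
    ids = index.ids
    pos = {t: i for i, t in enumerate(ids)}
    T = len(ids)
    members: list[np.ndarray] = []
    cvec: list[float] = []
    for ec, c in ecs.counts.items():
        for t in ec:
            if t not in pos:
                raise KeyError(f"equivalence class transcript {t} not in index")
        members.append(np.fromiter((pos[t] for t in ec), dtype=np.int64))
        cvec.append(float(c))
    counts_arr = np.asarray(cvec)
    N = counts_arr.sum()
    inv_l = np.array([1.0 / index.eff_lengths[t] for t in ids])
    trace: list[float] = []
    if N == 0:
        alpha = np.zeros(T)
        converged, it = True, 0
    else:
        alpha = np.full(T, N / T)
        converged = False
        it = 0
        log_n = np.log(N)
        for it in range(1, max_iter + 1):
            w = alpha * inv_l
            new = np.zeros(T)
            ll = 0.0
            for m, c in zip(members, counts_arr):
                denom = w[m].sum()
                new[m] += c * w[m] / denom
                ll += c * (np.log(denom) - log_n)
            trace.append(ll)
            rel = np.max(np.abs(new - alpha) / np.maximum(alpha, 1e-12))
            alpha = new
            if rel < tol:
                converged = True
                break
        if not converged:
            logger.warning(
                "EM did not converge after %d iterations (tol %.1e)",
                max_iter,
                tol,
            )
    df = pd.DataFrame(
        {
            "est_counts": alpha,
            "eff_length": [index.eff_lengths[t] for t in ids],
            "tpm": np.nan,
        },
        index=pd.Index(ids, name="transcript_id"),
    )
    return AbundanceTable(
        df=df, converged=converged, n_iter=it, loglik_trace=trace
    )


def compute_tpm(table: AbundanceTable) -> AbundanceTable:
    """Fill the TPM column: rate per effective length, scaled to 1e6.

    All-zero counts yield all-zero TPM (no division error).
    """
    rates = table.df["est_counts"] / table.df["eff_length"]
    total = rates.sum()
    table.df["tpm"] = 0.0 if total == 0 else 1e6 * rates / total
    return table


@dataclass(frozen=True)
class ExpressionCall:
    transcript_id: str
    tpm: float
    expressed: bool
    threshold: float = 1.0


def call_expressed(
    table: AbundanceTable, threshold: float = 1.0
) -> list[ExpressionCall]:
    """Call a transcript expressed iff TPM strictly exceeds the threshold."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if table.df["tpm"].isna().any():
        raise ValueError("TPM not computed; run compute_tpm first")
    return [
        ExpressionCall(
            transcript_id=t,
            tpm=float(v),
            expressed=bool(v > threshold),
            threshold=threshold,
        )
        for t, v in table.df["tpm"].items()
    ]


def fold_change(
    control: AbundanceTable, treated: AbundanceTable, pseudocount: float = 0.01
) -> pd.Series:
    """Per-transcript TPM ratio (treated + p) / (control + p)."""
    if set(control.df.index) != set(treated.df.index):
        raise ValueError("transcript sets differ between tables")
    t = treated.df["tpm"].reindex(control.df.index)
    c = control.df["tpm"]
    fc = (t + pseudocount) / (c + pseudocount)
    fc.name = "fold_change"
    return fc


def quantify_reads(
    reads: Iterable[str],
    index: KmerIndex,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
    condition: Optional[str] = None,
    cell_line: Optional[str] = None,
) -> AbundanceTable:
    """Pseudoalign, run EM, and normalize to TPM in one call."""
    ecs = pseudoalign(reads, index)
    table = em_abundances(ecs, index, tol=tol, max_iter=max_iter)
    table.condition = condition
    table.cell_line = cell_line
    return compute_tpm(table)


def utr_effect_experiment(
    reads: Sequence[str], cds_index: KmerIndex, utr_index: KmerIndex
) -> pd.DataFrame:
    """Quantify one read set against CDS-only and CDS+UTR indexes.

    Returns a table per inserted allele with ``tpm_cds_only``,
    ``tpm_with_utr`` and their ratio.  The two indexes must carry the
    same allele ids (same augmentation, differing only in whether allele
    sequences include untranslated regions).
    """
    if cds_index.allele_ids != utr_index.allele_ids:
        raise ValueError("allele ids differ between the two indexes")
    cds_tab = quantify_reads(reads, cds_index)
    utr_tab = quantify_reads(reads, utr_index)
    alleles = sorted(cds_index.allele_ids)
    tpm_cds = cds_tab.df.loc[alleles, "tpm"].to_numpy()
    tpm_utr = utr_tab.df.loc[alleles, "tpm"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(tpm_cds > 0, tpm_utr / tpm_cds, np.nan)
    return pd.DataFrame(
        {
            "tpm_cds_only": tpm_cds,
            "tpm_with_utr": tpm_utr,
            "ratio_utr_over_cds": ratio,
        },
        index=pd.Index(alleles, name="allele"),
    )
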