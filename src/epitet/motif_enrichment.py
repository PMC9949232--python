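"""Exhaustive k-mer enrichment against a dinucleotide-shuffled background.

A deliberately simple consensus-motif readout: count every k-mer in the
peak sequences (collapsing reverse complements in DNA mode; sense-strand
only in RNA mode, since RNA modifications sit on the transcript), compare
against the mean/sd of counts over seeded dinucleotide shuffles of the
same sequences, rank by z-score, and attach a Poisson upper-tail p-value
at the background mean with Benjamini-Hochberg adjustment across all
4^k k-mers. Dinucleotide shuffling preserves dinucleotide (and hence
mononucleotide) counts exactly, via a random Eulerian walk on the
de Bruijn multigraph of order 1.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter, defaultdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import ValidationError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
VALID = set("ACGT")


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _clean(seq: str) -> list[str]:
    """Uppercase, U->T; split at characters outside {A,C,G,T} (those
    positions are skipped with a warning by the caller)."""
    s = seq.upper().replace("U", "T")
    runs, cur = [], []
    for ch in s:
        if ch in VALID:
            cur.append(ch)
        else:
            if cur:
                runs.append("".join(cur))
            cur = []
    if cur:
        runs.append("".join(cur))
    return runs


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random sequence with exactly the dinucleotide counts of ``seq``
    (Altschul-Erickson): shuffle the outgoing-edge lists of the order-1
    de Bruijn multigraph, forcing, for every vertex other than the final
    one, a randomly chosen "last edge" that forms an in-tree to the final
    vertex (guaranteeing the walk is Eulerian), then walk from the
    original first character."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    vertices = list(edges.keys())
    # sample last-edges until they form an in-tree rooted at `last`
    while True:
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            outs = edges[v]
            last_edge[v] = outs[int(rng.integers(0, len(outs)))]
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        outs = list(edges[v])
        if v in last_edge:
            outs.remove(last_edge[v])
        perm = rng.permutation(len(outs))
        outs = [outs[i] for i in perm]
        if v in last_edge:
            outs.append(last_edge[v])
        shuffled[v] = outs
    out = [seq[0]]
    idx = defaultdict(int)
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    result = "".join(out)
    assert Counter(zip(result, result[1:])) == Counter(zip(seq, seq[1:])), (
        "shuffle failed to preserve dinucleotide counts"
    )
    return result


def _count_kmers(runs: Sequence[str], k: int, dna_mode: bool) -> Counter:
    c: Counter = Counter()
    for run in runs:
        for i in range(len(run) - k + 1):
            km = run[i : i + k]
            c[_canonical(km) if dna_mode else km] += 1
    return c


def kmer_enrichment(
    fg_sequences: Sequence[str],
    k: int = 6,
    background: str = "dinucleotide_shuffle",
    bg_sequences: Optional[Sequence[str]] = None,
    n_shuffles: int = 50,
    seed: int = 0,
    mode: str = "dna",
) -> pd.DataFrame:
    """k-mer enrichment table ranked by z-score.

    Columns: kmer, fg_count, bg_mean, bg_sd, z, pvalue, qvalue. Rows are
    sorted by descending z, ties broken lexicographically. ``mode="dna"``
    collapses reverse complements; ``mode="rna"`` counts the sense strand
    only. ``background="provided"`` uses ``bg_sequences`` directly (their
    counts scaled to the foreground position total); the default draws
    ``n_shuffles`` dinucleotide shuffles of the foreground.
    """
    if not 4 <= k <= 8:
        raise ValidationError("k must be in [4, 8]")
    if mode not in ("dna", "rna"):
        raise ValidationError("mode must be 'dna' or 'rna'")
    if background not in ("dinucleotide_shuffle", "provided"):
        raise ValidationError(f"unknown background {background!r}")
    dna_mode = mode == "dna"
    rng = np.random.default_rng(seed)

    fg_runs: list[str] = []
    skipped = 0
    for s in fg_sequences:
        runs = _clean(s)
        skipped += len(s) - sum(len(r) for r in runs)
        fg_runs.extend(runs)
    if skipped:
        warnings.warn(f"skipped {skipped} non-ACGT/U positions")
    fg = _count_kmers(fg_runs, k, dna_mode)
    n_fg_positions = sum(max(len(r) - k + 1, 0) for r in fg_runs)

    all_kmers = (
        sorted({_canonical("".join(t)) for t in itertools.product("ACGT", repeat=k)})
        if dna_mode
        else ["".join(t) for t in itertools.product("ACGT", repeat=k)]
    )
    kidx = {km: i for i, km in enumerate(all_kmers)}

    if background == "provided":
        if not bg_sequences:
            raise ValidationError("background='provided' needs bg_sequences")
        bg_runs = [r for s in bg_sequences for r in _clean(s)]
        bgc = _count_kmers(bg_runs, k, dna_mode)
        n_bg = sum(max(len(r) - k + 1, 0) for r in bg_runs)
        f = n_fg_positions / max(n_bg, 1)
        bg_mean = np.zeros(len(all_kmers))
        for km, c in bgc.items():
            bg_mean[kidx[km]] = c * f
        bg_sd = np.sqrt(np.maximum(bg_mean, 1.0))
    else:
        sums = np.zeros(len(all_kmers))
        sqs = np.zeros(len(all_kmers))
        for _ in range(n_shuffles):
            counts = np.zeros(len(all_kmers))
            shuf = [dinucleotide_shuffle(r, rng) for r in fg_runs]
            for km, c in _count_kmers(shuf, k, dna_mode).items():
                counts[kidx[km]] = c
            sums += counts
            sqs += counts**2
        bg_mean = sums / n_shuffles
        bg_sd = np.sqrt(np.maximum(sqs / n_shuffles - bg_mean**2, 0.0))

    fg_vec = np.zeros(len(all_kmers))
    for km, c in fg.items():
        fg_vec[kidx[km]] = c
    z = (fg_vec - bg_mean) / np.maximum(bg_sd, 1.0)
    # Poisson upper tail at an upper confidence bound of the estimated
    # background mean: guards against selecting, among 4^k tests, the
    # k-mers whose background happened to be underestimated
    n_eff = n_shuffles if background == "dinucleotide_shuffle" else 1
    lam = np.maximum(bg_mean + 2.0 * bg_sd / np.sqrt(n_eff), 1e-9)
    pv = stats.poisson.sf(fg_vec - 1.0, lam)
    pv = np.clip(pv, 0.0, 1.0)
    qv = stats.false_discovery_control(pv, method="bh")
    df = pd.DataFrame(
        {
            "kmer": all_kmers,
            "fg_count": fg_vec.astype(int),
            "bg_mean": bg_mean,
            "bg_sd": bg_sd,
            "z": z,
            "pvalue": pv,
            "qvalue": qv,
        }
    )
    df = df.sort_values(["z", "kmer"], ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)


def peak_sequences(
    genome: dict, peaks, flank: int = 50
) -> list[str]:
    """Sequence under each peak (summit +/- flank), for motif analysis."""
    out = []
    for p in peaks:
        seq = genome[p.chrom]
        s = max(0, p.summit - flank)
        e = min(len(seq), p.summit + flank)
        sub = seq[s:e]
        out.append(sub.decode() if isinstance(sub, (bytes, bytearray)) else sub)
    return out
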