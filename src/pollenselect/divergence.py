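"""Pairwise protein divergence: reciprocal-best-hit orthology, protein-
guided codon alignments, and counting-method dN/dS.

dN/dS uses Nei-Gojobori (1986) counting: per-codon synonymous site counts
from the fraction of one-step changes that are synonymous (changes to stop
codons count as nonsynonymous), observed differences resolved by equal-
weight averaging over all minimal substitution paths, and the Jukes-Cantor
correction d = -(3/4) ln(1 - 4p/3) applied to both proportions.  Pairs
with dS above a configurable ceiling (default 2) are flagged excluded, as
are saturated pairs where the correction is undefined (p >= 3/4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Sequence

import pandas as pd

from .codons import CODON_TO_AA, STOP_CODONS, codon_synonymous_sites
from .io_formats import HitRecord


@dataclass(frozen=True)
class OrthologPair:
    gene_id_a: str
    gene_id_b: str
    percent_identity: float
    aligned_length: int


@dataclass(frozen=True)
class DivergenceEstimate:
    gene_id_a: str
    gene_id_b: str
    dN: float
    dS: float
    omega: float  # nan when 0/0, +inf when dS=0 < dN
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    n_codons: int
    excluded: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------


def _best_hits(hits: Sequence[HitRecord]) -> dict[str, HitRecord]:
    """Top hit per query: highest bit score, ties broken by higher percent
    identity, then lexicographically smallest subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key = (h.bit_score, h.percent_identity)
        cur_key = (cur.bit_score, cur.percent_identity)
        if key > cur_key or (key == cur_key and h.subject_id < cur.subject_id):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
    min_identity: float = 30.0,
    min_length: int = 150,
) -> list[OrthologPair]:
    """Mutual best hits passing identity/length thresholds in both rows."""
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = []
    for a, hit in sorted(best_ab.items()):
        b = hit.subject_id
        back = best_ba.get(b)
        if back is None or back.subject_id != a:
            continue
        ok = all(
            h.percent_identity >= min_identity and h.aligned_length >= min_length
            for h in (hit, back)
        )
        if ok:
            pairs.append(
                OrthologPair(
                    gene_id_a=a,
                    gene_id_b=b,
                    percent_identity=hit.percent_identity,
                    aligned_length=hit.aligned_length,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# back-translation
# ---------------------------------------------------------------------------


def _trim_stop(cds: str) -> str:
    cds = cds.upper()
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def backtranslate_alignment(
    protein_aln_a: str,
    protein_aln_b: str,
    cds_a: str,
    cds_b: str,
) -> tuple[str, str]:
    """Replace each aligned amino acid by its source codon, gaps by ``---``.

    The ungapped proteins must translate exactly from their CDS (terminal
    stop trimmed); a mismatch raises with the offending position.
    """
    if len(protein_aln_a) != len(protein_aln_b):
        raise ValueError("protein alignment rows differ in length")
    out = []
    for aln, cds, name in ((protein_aln_a, cds_a, "a"), (protein_aln_b, cds_b, "b")):
        cds = _trim_stop(cds)
        if len(cds) % 3:
            raise ValueError(f"CDS {name} length not divisible by 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        ungapped = aln.replace("-", "")
        if len(ungapped) != len(codons):
            raise ValueError(
                f"protein {name} has {len(ungapped)} residues but CDS encodes {len(codons)}"
            )
        for pos, (aa, codon) in enumerate(zip(ungapped, codons)):
            if CODON_TO_AA.get(codon, "X") != aa.upper():
                raise ValueError(
                    f"protein {name} position {pos + 1}: residue {aa!r} does not "
                    f"match codon {codon!r}"
                )
        it = iter(codons)
        out.append("".join("---" if aa == "-" else next(it) for aa in aln))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Nei-Gojobori counting
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def codon_path_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weight over all minimal substitution paths.  Steps to or
    from a stop codon count as nonsynonymous."""
    diffs = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diffs:
        return 0.0, 0.0
    syn_total = 0.0
    non_total = 0.0
    n_paths = 0
    for order in permutations(diffs):
        cur = codon_a
        for p in order:
            nxt = cur[:p] + codon_b[p] + cur[p + 1 :]
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt] and nxt not in STOP_CODONS and cur not in STOP_CODONS:
                syn_total += 1
            else:
                non_total += 1
            cur = nxt
        n_paths += 1
    return syn_total / n_paths, non_total / n_paths


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differing sites; p in [0, 3/4)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise ValueError("proportion saturated (p >= 3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_dnds(
    codon_aln_a: str,
    codon_aln_b: str,
    ds_max: float = 2.0,
    gene_id_a: str = "a",
    gene_id_b: str = "b",
) -> DivergenceEstimate:
    """Nei-Gojobori dN and dS with Jukes-Cantor correction on a codon
    alignment.  Columns containing a gap, a stop codon, or an ambiguity
    code in either sequence are dropped pairwise."""
    if len(codon_aln_a) != len(codon_aln_b) or len(codon_aln_a) % 3:
        raise ValueError("codon alignment rows must be equal length multiples of 3")
    s_sites = n_sites = 0.0
    s_diffs = n_diffs = 0.0
    n_codons = 0
    for i in range(0, len(codon_aln_a), 3):
        ca = codon_aln_a[i : i + 3].upper()
        cb = codon_aln_b[i : i + 3].upper()
        if "-" in ca or "-" in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        if any(b not in "ACGT" for b in ca + cb):
            continue
        n_codons += 1
        s_sites += (codon_synonymous_sites(ca) + codon_synonymous_sites(cb)) / 2.0
        sd, nd = codon_path_counts(ca, cb)
        s_diffs += sd
        n_diffs += nd
    n_sites = 3.0 * n_codons - s_sites

    def make(dN, dS, omega, excluded, reason=""):
        return DivergenceEstimate(
            gene_id_a=gene_id_a, gene_id_b=gene_id_b, dN=dN, dS=dS, omega=omega,
            n_sites=n_sites, s_sites=s_sites, n_diffs=n_diffs, s_diffs=s_diffs,
            n_codons=n_codons, excluded=excluded, reason=reason,
        )

    if n_codons == 0:
        return make(math.nan, math.nan, math.nan, True, "no_comparable_codons")
    pS = s_diffs / s_sites if s_sites > 0 else 0.0
    pN = n_diffs / n_sites if n_sites > 0 else 0.0
    try:
        dS = jukes_cantor(pS)
        dN = jukes_cantor(pN)
    except ValueError:
        return make(math.nan, math.nan, math.nan, True, "saturated")
    if dS == 0.0:
        omega = math.nan if dN == 0.0 else math.inf
        return make(dN, dS, omega, True, "ds_zero")
    omega = dN / dS
    if dS > ds_max:
        return make(dN, dS, omega, True, f"ds_above_{ds_max:g}")
    return make(dN, dS, omega, False)


def dnds_from_cds_pair(
    cds_a: str,
    cds_b: str,
    ds_max: float = 2.0,
    gene_id_a: str = "a",
    gene_id_b: str = "b",
) -> DivergenceEstimate:
    """dN/dS for two equal-length, gap-free orthologous CDS (identity
    protein alignment)."""
    a, b = _trim_stop(cds_a), _trim_stop(cds_b)
    if len(a) != len(b):
        raise ValueError("CDS lengths differ; supply an explicit alignment")
    return pairwise_dnds(a, b, ds_max=ds_max, gene_id_a=gene_id_a, gene_id_b=gene_id_b)


def divergence_table(
    cds_a: dict[str, str],
    cds_b: dict[str, str],
    pairs: Sequence[OrthologPair],
    ds_max: float = 2.0,
) -> pd.DataFrame:
    """Per-pair dN/dS for reciprocal-best-hit orthologs with identical
    protein lengths (alignment-free path)."""
    rows = []
    for p in pairs:
        est = dnds_from_cds_pair(
            cds_a[p.gene_id_a], cds_b[p.gene_id_b], ds_max=ds_max,
            gene_id_a=p.gene_id_a, gene_id_b=p.gene_id_b,
        )
        rows.append(
            (est.gene_id_a, est.gene_id_b, est.dN, est.dS, est.omega,
             est.n_sites, est.s_sites, est.n_diffs, est.s_diffs,
             est.excluded, est.reason)
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id_a", "gene_id_b", "dN", "dS", "omega",
                 "n_sites", "s_sites", "n_diffs", "s_diffs", "excluded", "reason"],
    )
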