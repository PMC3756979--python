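"""Genetic-code tables and codon-model structure matrices.

Everything downstream of the codon substitution model (simulation, ML
fitting, NG86 site counting) shares the static structure computed here:
the 61 sense codons of the universal code, and for every ordered codon
pair differing at exactly one position whether that change is a
transition or a transversion and whether it is synonymous.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

NUCLEOTIDES = "TCAG"

#: Universal genetic code, codon -> amino acid ('*' = stop).
GENETIC_CODE: dict[str, str] = {}
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _n1 in enumerate(NUCLEOTIDES):
    for _j, _n2 in enumerate(NUCLEOTIDES):
        for _k, _n3 in enumerate(NUCLEOTIDES):
            GENETIC_CODE[_n1 + _n2 + _n3] = _AA[16 * _i + 4 * _j + _k]

STOP_CODONS = frozenset(c for c, a in GENETIC_CODE.items() if a == "*")

#: The 61 sense codons in fixed (TCAG-major) order.
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

_PURINES = frozenset("AG")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def translate(cds: str) -> str:
    """Translate a CDS (length divisible by 3) to protein, '*' for stops."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    cds = cds.upper().replace("U", "T")
    return "".join(GENETIC_CODE.get(cds[i : i + 3], "X") for i in range(0, len(cds), 3))


def codons_of(cds: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def check_no_internal_stops(cds: str, name: str = "sequence") -> None:
    cod = codons_of(cds)
    for i, c in enumerate(cod[:-1]):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} at codon {i} in {name}")
    if cod and cod[-1] in STOP_CODONS:
        # trailing stop is allowed on input CDS but excluded from modelling
        pass


@lru_cache(maxsize=1)
def codon_structure() -> dict[str, np.ndarray]:
    """Structure masks over ordered sense-codon pairs (61 x 61 boolean).

    Keys: ``single`` (exactly one nucleotide differs), ``transition``,
    ``transversion``, ``synonymous``, ``nonsynonymous`` — the latter four
    all imply ``single``.
    """
    n = N_CODONS
    single = np.zeros((n, n), dtype=bool)
    ts = np.zeros((n, n), dtype=bool)
    syn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            ts[i, j] = is_transition(a, b)
            syn[i, j] = GENETIC_CODE[ci] == GENETIC_CODE[cj]
    return {
        "single": single,
        "transition": ts,
        "transversion": single & ~ts,
        "synonymous": syn,
        "nonsynonymous": single & ~syn,
    }


def rate_matrix(kappa: float, omega: float, freqs: np.ndarray | None = None) -> np.ndarray:
    """GY94-style 61x61 rate matrix Q, scaled to one expected substitution
    per codon per unit time at stationarity.

    q_ij = pi_j * (kappa if transition) * (omega if nonsynonymous) for
    single-nucleotide changes, 0 otherwise.  ``freqs`` defaults to equal
    codon frequencies (1/61), under which Q is symmetric.
    """
    s = codon_structure()
    if freqs is None:
        freqs = np.full(N_CODONS, 1.0 / N_CODONS)
    freqs = np.asarray(freqs, dtype=float)
    q = np.where(s["single"], 1.0, 0.0)
    q = np.where(s["transition"], q * kappa, q)
    q = np.where(s["nonsynonymous"], q * omega, q)
    q = q * freqs[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(freqs * np.diag(q)).sum()
    if scale > 0:
        q /= scale
    return q


def transition_probabilities(q: np.ndarray, t: float, freqs: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt) via symmetric eigendecomposition.

    Q is reversible; with stationary frequencies pi, the matrix
    diag(pi)^1/2 Q diag(pi)^-1/2 is symmetric, so exp(Qt) is obtained
    from one `eigh` per Q and is exact for any t.
    """
    if freqs is None:
        freqs = np.full(N_CODONS, 1.0 / N_CODONS)
    sq = np.sqrt(freqs)
    sym = q * (sq[:, None] / sq[None, :])
    sym = 0.5 * (sym + sym.T)
    w, v = np.linalg.eigh(sym)
    p = (v * np.exp(w * t)) @ v.T
    p = p * (sq[None, :] / sq[:, None])
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def f3x4_frequencies(cds_list: list[str]) -> np.ndarray:
    """F3x4 codon frequencies: per-position nucleotide frequencies
    multiplied and renormalized over sense codons."""
    counts = np.zeros((3, 4))
    nt_idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for cds in cds_list:
        for codon in codons_of(cds.replace("-", "")):
            if codon in GENETIC_CODE:
                for pos, nt in enumerate(codon):
                    if nt in nt_idx:
                        counts[pos, nt_idx[nt]] += 1
    rowsums = counts.sum(axis=1, keepdims=True)
    rowsums[rowsums == 0] = 1.0
    props = counts / rowsums
    freqs = np.array(
        [
            props[0, nt_idx[c[0]]] * props[1, nt_idx[c[1]]] * props[2, nt_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    total = freqs.sum()
    if total == 0:
        return np.full(N_CODONS, 1.0 / N_CODONS)
    return freqs / total
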