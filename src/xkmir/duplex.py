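"""Intermolecular miRNA:mRNA duplex folding by a constrained nearest-neighbor DP.

The model scores a single antiparallel intermolecular helix system: an ordered
chain of base pairs, strictly increasing along the miRNA (5'->3') and strictly
decreasing along the target.  Energy decomposes as

    E = helix_init + sum(stack energies over adjacent pairs)
                   + sum(affine bulge / internal-loop penalties)

with unpaired terminal nucleotides free.  Admissible pairs are the Watson-Crick
pairs plus the G·U wobble.  Intramolecular structure, dangling ends and
pseudoknots are outside the model by design: the quantity of interest is the
stability of the miRNA:target hybrid alone.

Two seed constraints mirror the biological filtering rules:

* ``require_seed_wc`` — miRNA nucleotides 2-7 (1-based) must each be paired,
  by Watson-Crick pairs ("perfect matching in the seed region");
* ``forbid_seed_gu`` — no G·U pair may occur at miRNA nucleotides 2-7.

``hybridize`` computes the constrained minimum free energy by dynamic
programming over chain-final pairs; ``brute_force_mfe`` is an exhaustive
enumeration of every admissible chain on tiny instances and serves as the
independent oracle.  Both accumulate energy in chain order so co-optimal
structures tie bit-for-bit, and ties are broken by the lexicographically
smallest pair list for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .io_formats import MatureMiRNA, TranscriptRecord
from .sites import SeedMatch

WC_PAIRS = frozenset({"AU", "UA", "CG", "GC"})
WOBBLE_PAIRS = frozenset({"GU", "UG"})
ADMISSIBLE_PAIRS = WC_PAIRS | WOBBLE_PAIRS

# Seed = miRNA nt 2-7, 1-based; as 0-based indices:
_SEED_IDX = frozenset(range(1, 7))

# Watson-Crick/Watson-Crick stacking free energies (kcal/mol, 37 C), standard
# published nearest-neighbor values.  Key (p1, p2): adjacent pairs with p1 the
# 5'-side pair on the miRNA strand; each pair is written miRNA-base +
# target-base.  The duplex 5'AB3'/3'A'B'5' equals 5'B'A'3'/3'BA5' read from
# the other strand, which fixes the symmetric entries.
_WC_STACKS = {
    ("AU", "AU"): -0.93,  # 5'AA3'/3'UU5'
    ("UA", "UA"): -0.93,
    ("AU", "UA"): -1.10,  # 5'AU3'/3'UA5'
    ("UA", "AU"): -1.33,  # 5'UA3'/3'AU5'
    ("CG", "UA"): -2.08,  # 5'CU3'/3'GA5'
    ("AU", "GC"): -2.08,
    ("CG", "AU"): -2.11,  # 5'CA3'/3'GU5'
    ("UA", "GC"): -2.11,
    ("GC", "UA"): -2.24,  # 5'GU3'/3'CA5'
    ("AU", "CG"): -2.24,
    ("GC", "AU"): -2.35,  # 5'GA3'/3'CU5'
    ("UA", "CG"): -2.35,
    ("CG", "GC"): -2.36,  # 5'CG3'/3'GC5'
    ("GC", "GC"): -3.26,  # 5'GG3'/3'CC5'
    ("CG", "CG"): -3.26,
    ("GC", "CG"): -3.42,  # 5'GC3'/3'CG5'
}


def _default_stack_table() -> dict[tuple[str, str], float]:
    """WC stacks from the published table; wobble-containing stacks are
    assigned flat documented defaults (-1.2 with one wobble, -0.4 with two)."""
    table = dict(_WC_STACKS)
    for p1 in ADMISSIBLE_PAIRS:
        for p2 in ADMISSIBLE_PAIRS:
            if (p1, p2) in table:
                continue
            n_wobble = (p1 in WOBBLE_PAIRS) + (p2 in WOBBLE_PAIRS)
            table[(p1, p2)] = -1.2 if n_wobble == 1 else -0.4
    return table


@dataclass(frozen=True)
class EnergyParameters:
    """Configurable nearest-neighbor energy model.

    ``bulge_penalty(s) = bulge_open + bulge_per_nt * s`` and likewise for
    internal loops, with ``s`` the total number of unpaired nucleotides
    enclosed between two consecutive pairs.
    """

    stack_energy: dict[tuple[str, str], float] = field(
        default_factory=_default_stack_table
    )
    helix_init: float = 4.09
    bulge_open: float = 3.5
    bulge_per_nt: float = 0.4
    internal_open: float = 4.0
    internal_per_nt: float = 0.3
    max_bulge: int = 15
    max_internal_loop: int = 15

    def __post_init__(self) -> None:
        if self.max_bulge < 1 or self.max_internal_loop < 1:
            raise ValueError("loop size bounds must be >= 1")
        if min(self.bulge_open, self.bulge_per_nt, self.internal_open, self.internal_per_nt) < 0:
            raise ValueError("loop penalties must be non-negative")
        for (p1, p2), e in self.stack_energy.items():
            if p1 in WC_PAIRS and p2 in WC_PAIRS and e > 0:
                raise ValueError(f"WC/WC stack {p1}/{p2} must be <= 0, got {e}")

    def bulge_penalty(self, size: int) -> float:
        return self.bulge_open + self.bulge_per_nt * size

    def internal_loop_penalty(self, size: int) -> float:
        return self.internal_open + self.internal_per_nt * size


def load_params(path: str | Path) -> EnergyParameters:
    """Load an energy-parameter TSV: ``stack<TAB>p1<TAB>p2<TAB>value`` rows plus
    ``scalar<TAB>name<TAB>value`` rows; unlisted stacks keep the defaults."""
    stacks = _default_stack_table()
    scalars: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "stack" and len(parts) == 4:
                stacks[(parts[1], parts[2])] = float(parts[3])
            elif parts[0] == "scalar" and len(parts) >= 3:
                scalars[parts[1]] = float(parts[2])
            else:
                raise ValueError(f"{path}:{lineno}: bad parameter row {line!r}")
    ints = {k: int(v) for k, v in scalars.items() if k in ("max_bulge", "max_internal_loop")}
    floats = {k: v for k, v in scalars.items() if k not in ints}
    return EnergyParameters(stack_energy=stacks, **floats, **ints)


def write_params(params: EnergyParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\ta\tb\tvalue\n")
        for (p1, p2), e in sorted(params.stack_energy.items()):
            fh.write(f"stack\t{p1}\t{p2}\t{e}\n")
        for name in ("helix_init", "bulge_open", "bulge_per_nt", "internal_open",
                     "internal_per_nt", "max_bulge", "max_internal_loop"):
            fh.write(f"scalar\t{name}\t{getattr(params, name)}\t\n")


@dataclass(frozen=True)
class TargetWindow:
    """A transcript subsequence localized around a seed-match anchor."""

    transcript_id: str
    window_start: int
    window_end: int
    sequence: str


def make_window(
    transcript: TranscriptRecord,
    seed_match: SeedMatch,
    mirna_length: int,
    flank: int = 10,
) -> TargetWindow:
    """Window around a seed match with room for 3'-miRNA pairing and bulges.

    The miRNA binds antiparallel with nt 2-13 opposite the matched 12-mer, so
    nt 14..L pair 5'-ward of the site (lower target coordinates) and nt 1
    pairs one base 3'-ward; ``flank`` adds slack for bulges on either side.
    """
    start = max(0, seed_match.site_start - (mirna_length - 13) - flank)
    end = min(len(transcript.sequence), seed_match.site_end + 1 + flank)
    return TargetWindow(
        transcript_id=transcript.transcript_id,
        window_start=start,
        window_end=end,
        sequence=transcript.sequence[start:end],
    )


@dataclass(frozen=True)
class DuplexStructure:
    """A folded miRNA:target duplex.

    ``pairs`` lists (miRNA position, target position) with miRNA positions
    1-based and strictly increasing, target positions 0-based and strictly
    decreasing (antiparallel).  Target positions are window-local when the
    duplex was computed against a bare sequence and transcript-local when
    computed against a :class:`TargetWindow`.
    """

    pairs: tuple[tuple[int, int], ...]
    mfe: float
    seed_perfect: bool
    seed_gu_free: bool
    diagram: str = ""


def _pair_of(mirna: str, target: str, i: int, j: int) -> str | None:
    p = mirna[i] + target[j]
    return p if p in ADMISSIBLE_PAIRS else None


def _transition_cost(
    params: EnergyParameters, p_prev: str, p_next: str, di: int, dj: int
) -> float | None:
    """Energy of moving from one pair to the next; None if inadmissible.

    ``di``/``dj`` are the unpaired nucleotide counts on the miRNA / target
    side between the two pairs.
    """
    if di == 0 and dj == 0:
        return params.stack_energy[(p_prev, p_next)]
    size = di + dj
    if di == 0 or dj == 0:
        if size > params.max_bulge:
            return None
        return params.bulge_penalty(size)
    if size > params.max_internal_loop:
        return None
    return params.internal_loop_penalty(size)


def _seed_pair_ok(
    pair: str, i: int, require_seed_wc: bool, forbid_seed_gu: bool
) -> bool:
    if i in _SEED_IDX:
        if require_seed_wc and pair not in WC_PAIRS:
            return False
        if forbid_seed_gu and pair in WOBBLE_PAIRS:
            return False
    return True


def _finalize(
    mirna: str,
    target: str,
    chain: tuple[tuple[int, int], ...],
    energy: float,
    offset: int,
) -> DuplexStructure:
    paired = {i: mirna[i] + target[j] for i, j in chain}
    seed_perfect = all(i in paired and paired[i] in WC_PAIRS for i in _SEED_IDX)
    seed_gu_free = all(
        paired[i] not in WOBBLE_PAIRS for i in _SEED_IDX if i in paired
    )
    out_pairs = tuple((i + 1, j + offset) for i, j in chain)
    diagram = _render_diagram(mirna, target, chain)
    return DuplexStructure(
        pairs=out_pairs,
        mfe=energy,
        seed_perfect=seed_perfect,
        seed_gu_free=seed_gu_free,
        diagram=diagram,
    )


def hybridize(
    mirna: MatureMiRNA | str,
    window: TargetWindow | str,
    params: EnergyParameters | None = None,
    require_seed_wc: bool = False,
    forbid_seed_gu: bool = False,
) -> DuplexStructure | None:
    """Minimum-free-energy duplex under the seed constraints, or None.

    Returns ``None`` ("no structure") when no admissible >=1-pair chain
    satisfies the constraints — deliberately distinct from an MFE of zero so
    downstream thresholds can never accidentally pass.
    """
    params = params or EnergyParameters()
    mseq = mirna if isinstance(mirna, str) else mirna.sequence
    tseq = window if isinstance(window, str) else window.sequence
    offset = 0 if isinstance(window, str) else window.window_start
    if require_seed_wc and len(mseq) < 7:
        raise ValueError("require_seed_wc needs a miRNA of length >= 7")
    if not tseq:
        raise ValueError("empty target window")
    m, w = len(mseq), len(tseq)
    required = sorted(_SEED_IDX) if require_seed_wc else []
    # req_before[k] = number of required miRNA indices < k
    req_before = [0] * (m + 2)
    for k in range(1, m + 2):
        req_before[k] = req_before[k - 1] + (1 if (k - 1) in _SEED_IDX and required else 0)

    max_span = max(params.max_bulge, params.max_internal_loop)
    # dp[(i, j)] = (energy, chain) of the best chain whose last pair is (i, j)
    dp: dict[tuple[int, int], tuple[float, tuple[tuple[int, int], ...]]] = {}
    pair_at: dict[tuple[int, int], str] = {}
    for i in range(m):
        for j in range(w):
            p = _pair_of(mseq, tseq, i, j)
            if p is None or not _seed_pair_ok(p, i, require_seed_wc, forbid_seed_gu):
                continue
            pair_at[(i, j)] = p
            best: tuple[float, tuple[tuple[int, int], ...]] | None = None
            if req_before[i] == 0:  # chain may start here
                best = (params.helix_init, ((i, j),))
            for ip in range(max(0, i - 1 - max_span), i):
                if req_before[i] - req_before[ip + 1] > 0:
                    continue  # a required seed position would be skipped
                for jp in range(j + 1, min(w, j + 2 + max_span)):
                    prev = dp.get((ip, jp))
                    if prev is None:
                        continue
                    cost = _transition_cost(
                        params, pair_at[(ip, jp)], p, i - ip - 1, jp - j - 1
                    )
                    if cost is None:
                        continue
                    cand = (prev[0] + cost, prev[1] + ((i, j),))
                    if best is None or cand < best:
                        best = cand
            if best is not None:
                dp[(i, j)] = best

    final: tuple[float, tuple[tuple[int, int], ...]] | None = None
    for (i, j), (energy, chain) in dp.items():
        if required and req_before[m] - req_before[i + 1] > 0:
            continue  # required positions remain unpaired after the last pair
        cand = (energy, chain)
        if final is None or cand < final:
            final = cand
    if final is None:
        return None
    return _finalize(mseq, tseq, final[1], final[0], offset)


_BRUTE_MAX_MIRNA = 10
_BRUTE_MAX_WINDOW = 12


def brute_force_mfe(
    mirna: MatureMiRNA | str,
    window: TargetWindow | str,
    params: EnergyParameters | None = None,
    require_seed_wc: bool = False,
    forbid_seed_gu: bool = False,
) -> DuplexStructure | None:
    """Exhaustive enumeration of every admissible chain; the test oracle.

    Identical contract to :func:`hybridize` but restricted to tiny instances
    (miRNA <= 10 nt, window <= 12 nt) so full enumeration stays feasible.
    """
    params = params or EnergyParameters()
    mseq = mirna if isinstance(mirna, str) else mirna.sequence
    tseq = window if isinstance(window, str) else window.sequence
    offset = 0 if isinstance(window, str) else window.window_start
    if len(mseq) > _BRUTE_MAX_MIRNA or len(tseq) > _BRUTE_MAX_WINDOW:
        raise ValueError(
            f"brute_force_mfe bound exceeded: {len(mseq)} x {len(tseq)}"
        )
    m, w = len(mseq), len(tseq)
    required = _SEED_IDX if require_seed_wc else frozenset()

    cells = []
    for i in range(m):
        for j in range(w):
            p = _pair_of(mseq, tseq, i, j)
            if p is not None and _seed_pair_ok(p, i, require_seed_wc, forbid_seed_gu):
                cells.append((i, j, p))

    best: tuple[float, tuple[tuple[int, int], ...]] | None = None

    def valid_end(i: int) -> bool:
        return not any(r > i for r in required)

    def extend(
        chain: tuple[tuple[int, int], ...], energy: float, last_i: int, last_j: int, last_p: str
    ) -> None:
        nonlocal best
        if valid_end(last_i):
            cand = (energy, chain)
            if best is None or cand < best:
                best = cand
        for i, j, p in cells:
            if i <= last_i or j >= last_j:
                continue
            if any(last_i < r < i for r in required):
                continue
            cost = _transition_cost(params, last_p, p, i - last_i - 1, last_j - j - 1)
            if cost is None:
                continue
            extend(chain + ((i, j),), energy + cost, i, j, p)

    for i, j, p in cells:
        if any(r < i for r in required):
            continue
        extend(((i, j),), params.helix_init, i, j, p)

    if best is None:
        return None
    return _finalize(mseq, tseq, best[1], best[0], offset)


def passes_criteria(
    duplex: DuplexStructure | None, mfe_threshold: float | None = -25.0
) -> bool:
    """Apply the interaction-selection criteria to a folded duplex.

    True iff the duplex exists, the seed (nt 2-7) is perfectly Watson-Crick
    paired, it contains no seed G·U, and — unless the threshold is disabled
    with ``None`` — its MFE is strictly below ``mfe_threshold``.
    """
    if duplex is None:
        return False
    if not (duplex.seed_perfect and duplex.seed_gu_free):
        return False
    if mfe_threshold is None:
        return True
    return duplex.mfe < mfe_threshold


def _render_diagram(
    mirna: str, target: str, chain: Sequence[tuple[int, int]]
) -> str:
    """Four-line text rendering: target (5'->3') on top, miRNA (3'->5') below,
    with paired bases pulled onto the two inner rows."""
    t_up: list[str] = []  # unpaired target
    t_pr: list[str] = []  # paired target
    m_pr: list[str] = []  # paired miRNA
    m_up: list[str] = []  # unpaired miRNA

    def emit(tu: str, tp: str, mp: str, mu: str) -> None:
        t_up.append(tu)
        t_pr.append(tp)
        m_pr.append(mp)
        m_up.append(mu)

    def emit_loop(t_frag: str, m_frag: str) -> None:
        # m_frag arrives 5'->3'; the miRNA row renders 3'->5'
        n = max(len(t_frag), len(m_frag))
        t_frag = t_frag.ljust(n)
        m_frag = m_frag[::-1].ljust(n)
        for a, b in zip(t_frag, m_frag):
            emit(a, " ", " ", b)

    first_i, first_j = chain[0]
    # leading unpaired: target 5' of the deepest pair; miRNA 3' tail
    lead_t = target[:chain[-1][1]]
    lead_m = mirna[chain[-1][0] + 1 :]
    emit_loop(lead_t, lead_m)
    # walk the chain from the last pair (lowest target coord) back to the first
    rev = list(chain)[::-1]
    for k, (i, j) in enumerate(rev):
        emit(" ", target[j], mirna[i], " ")
        if k + 1 < len(rev):
            ni, nj = rev[k + 1]
            emit_loop(target[j + 1 : nj], mirna[ni + 1 : i])
    trail_t = target[first_j + 1 :]
    trail_m = mirna[:first_i]
    emit_loop(trail_t, trail_m)
    lines = [
        "target 5' " + "".join(t_up) + " 3'",
        "          " + "".join(t_pr),
        "          " + "".join(m_pr),
        "miRNA  3' " + "".join(m_up) + " 5'",
    ]
    return "\n".join(lines)
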