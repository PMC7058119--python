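"""Solution-space analysis for the subclonal-frequency equation set.

For a segment with average copy number cbar and folded average BAF
values {mu_hat_k}, the pair (subclonal frequency phi, absolute copy
number C with genotype BAF mu) must satisfy

    cbar = phi * C + (1 - phi) * 2
    cbar * mu_bar_k = phi * C * mu_k + (1 - phi)        (k = 1..K)

Two distinct (C, mu) pairs can explain the same observation exactly when
they share the invariant

    xi = (C * mu_hat - 1) / (C - 2),

in which case the observation lies on the curve
mu_bar_hat(cbar) = xi * (1 - 2/cbar) + 1/cbar and each member yields its
own phi = (cbar - 2)/(C - 2). The case structure:

* cbar < 2                          -> a single phi
* cbar > 2 and cbar < 1/mu_bar_hat  -> a single phi
* cbar > 2 and cbar >= 1/mu_bar_hat -> infinitely many (C, mu, phi)
  without a copy-number cap; finitely many under a cap C <= c_max, and
  only the curves with >= 2 realizable members in the admissible region
  cbar in (2, min C) actually present multiple phi.

Curve grouping uses exact rational arithmetic: floating-point grouping
would split equal curves. The family is enumerated over genotype-
realizable pairs (C, mu_hat = min(n_M, n_P)/C); whether the deletion
copy numbers C = 0 (empty genotype, mu_hat taken as 0) and C = 1
(mu_hat = 0) join the family is exposed as flags, defaulting to C = 0
in and C = 1 out — the convention under which the family at c_max = 15
has 43 curves, 7 of them multi-solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

_ATOL = 1e-9


class NeutralCopyNumberError(ValueError):
    """C = 2 makes the first equation hold for every phi."""


@dataclass(frozen=True)
class Curve:
    """One member family sharing an exact xi value."""

    xi: Fraction
    members: tuple[tuple[int, Fraction], ...]  # (C, mu_hat)

    def mu_bar_hat(self, cbar: float) -> float:
        """Folded average BAF the curve predicts at a given cbar."""
        return float(self.xi) * (1.0 - 2.0 / cbar) + 1.0 / cbar


@dataclass
class SolutionReport:
    count_class: str  # "unique" | "multiple" | "infinite"
    solutions: list[tuple[float, int, float | None]]  # (phi, C, mu_T)
    xi: list[float | None]
    infinite_without_cmax: bool = False


def phi_from_avg_copy(cbar: float, c: int) -> float:
    """Invert cbar = phi*C + (1-phi)*2 for phi. Caller checks [0, 1]."""
    if c == 2:
        raise NeutralCopyNumberError(
            "C = 2: any phi satisfies the average-copy equation"
        )
    if c < 0:
        raise ValueError("copy number must be >= 0")
    return (cbar - 2.0) / (c - 2.0)


def xi_value(c: int, mu_hat: float) -> float:
    """The curve invariant (C*mu_hat - 1)/(C - 2)."""
    if c == 2:
        raise NeutralCopyNumberError("xi undefined at C = 2")
    if c < 0:
        raise ValueError("copy number must be >= 0")
    return (c * mu_hat - 1.0) / (c - 2.0)


def _folded_mu_options(c: int) -> list[Fraction]:
    """Folded genotype BAFs min(n_M, n_P)/C for all genotypes of C."""
    if c == 0:
        return [Fraction(0)]
    return [Fraction(k, c) for k in range(c // 2 + 1)]


def _expected_folded_baf(phi: float, c: int, mu: float) -> float:
    cbar = phi * c + (1.0 - phi) * 2.0
    if cbar == 0.0:
        return 0.5
    m = (phi * c * mu + (1.0 - phi)) / cbar
    return min(m, 1.0 - m)


def classify_solutions(
    cbar: float, baf_hats: list[float], c_max: int, atol: float = _ATOL
) -> SolutionReport:
    """Enumerate all (phi, C, mu) triples explaining (cbar, {mu_bar_hat_k}).

    Brute force over C in {0..c_max} \\ {2} and genotype-derived mu: a
    triple qualifies when phi = (cbar-2)/(C-2) lies in [0, 1] and every
    observed folded BAF is matched by some genotype of C at that phi.
    The class is "unique" for one distinct phi, else "multiple";
    ``infinite_without_cmax`` flags the regime where lifting the cap
    admits infinitely many solutions (cbar > 2 and cbar >= 1/mu_bar_hat).
    """
    if c_max < 3:
        raise ValueError("c_max must be >= 3")
    if cbar <= 0:
        raise ValueError("cbar must be positive")
    for mh in baf_hats:
        if not -atol <= mh <= 0.5 + atol:
            raise ValueError(f"folded BAF {mh} outside [0, 0.5]")

    if abs(cbar - 2.0) <= atol:
        # phi = 0 (or neutral C = 2): copy-neutral observation
        return SolutionReport(
            count_class="unique", solutions=[(0.0, 2, None)], xi=[None]
        )

    infinite = cbar > 2.0 and any(
        mh > atol and cbar >= 1.0 / mh - atol for mh in baf_hats
    )

    solutions: list[tuple[float, int, float | None]] = []
    xis: list[float | None] = []
    for c in range(0, c_max + 1):
        if c == 2:
            continue
        phi = phi_from_avg_copy(cbar, c)
        if not -atol <= phi <= 1.0 + atol:
            continue
        phi = min(max(phi, 0.0), 1.0)
        matched: list[float] = []
        ok = True
        for mh in baf_hats:
            hit = None
            for mu in _folded_mu_options(c):
                if abs(_expected_folded_baf(phi, c, float(mu)) - mh) <= atol:
                    hit = float(mu)
                    break
            if hit is None:
                ok = False
                break
            matched.append(hit)
        if ok:
            solutions.append((phi, c, matched[0] if matched else None))
            xis.append(xi_value(c, matched[0]) if matched else None)
    order = np.argsort([s[0] for s in solutions]) if solutions else []
    solutions = [solutions[i] for i in order]
    xis = [xis[i] for i in order]
    distinct_phi = {round(s[0], 9) for s in solutions}
    if len(distinct_phi) <= 1:
        count_class = "unique"
    else:
        count_class = "infinite" if infinite else "multiple"
    return SolutionReport(
        count_class=count_class,
        solutions=solutions,
        xi=xis,
        infinite_without_cmax=infinite,
    )


def enumerate_curves(
    c_max: int,
    include_homozygous_deletion: bool = True,
    include_hemizygous_deletion: bool = False,
) -> list[Curve]:
    """Enumerate the xi-curve family up to ``c_max``, grouped by exact
    rational xi and sorted by xi."""
    if c_max < 3:
        raise ValueError("c_max must be >= 3")
    copy_numbers = []
    if include_homozygous_deletion:
        copy_numbers.append(0)
    if include_hemizygous_deletion:
        copy_numbers.append(1)
    copy_numbers.extend(range(3, c_max + 1))
    groups: dict[Fraction, list[tuple[int, Fraction]]] = {}
    for c in copy_numbers:
        for mu in _folded_mu_options(c):
            xi = (c * mu - 1) / Fraction(c - 2)
            groups.setdefault(xi, []).append((c, mu))
    return [
        Curve(xi=xi, members=tuple(sorted(groups[xi])))
        for xi in sorted(groups)
    ]


def curve_has_multiple_solutions(curve: Curve, n_probe: int = 9) -> bool:
    """Whether some admissible observation on the curve is explained by
    two members with distinct phi.

    Probes cbar values inside (2, min(C', C'')) for every member pair
    with distinct copy numbers >= 3 and checks the predicted folded BAF
    is admissible (in [0, 0.5]); distinct C at the same cbar always give
    distinct phi.
    """
    cs = sorted({c for c, _ in curve.members if c >= 3})
    for i in range(len(cs)):
        for j in range(i + 1, len(cs)):
            hi = min(cs[i], cs[j])
            for t in np.linspace(0.0, 1.0, n_probe + 2)[1:-1]:
                cbar = 2.0 + (hi - 2.0) * float(t)
                if 0.0 <= curve.mu_bar_hat(cbar) <= 0.5:
                    return True
    return False


def count_multi_solution_curves(
    c_max: int,
    include_homozygous_deletion: bool = True,
    include_hemizygous_deletion: bool = False,
) -> int:
    """Number of curves in the family presenting multiple phi solutions
    under the ``c_max`` restriction."""
    curves = enumerate_curves(
        c_max, include_homozygous_deletion, include_hemizygous_deletion
    )
    return sum(curve_has_multiple_solutions(c) for c in curves)
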