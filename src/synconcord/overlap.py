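"""Gene-list overlap statistics and ribosomal-protein tagging.

Quantifies how much of an up-regulated proteome is explained by direct
scaffold interaction: the intersection of the up-regulated protein list with
a scaffold interactome, reported as a count and as a percentage of the
up-regulated list (the headline denominator). An optional hypergeometric
upper-tail test gives a calibrated null when the user supplies a universe
size. Ribosomal-protein tagging counts identifiers under the standard
cytosolic/mitochondrial RP gene nomenclature prefixes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from .errors import InputError, ParameterError
from .quantify import normalize_identifier

logger = logging.getLogger(__name__)

#: Cytosolic (Rpl*/Rps*) and mitochondrial (Mrpl*/Mrps*) RP gene-symbol
#: prefixes, lowercase; ``rplp`` (the P-stalk proteins) is covered by ``rpl``.
DEFAULT_RP_PREFIXES = ("rpl", "rps", "mrpl", "mrps")


@dataclass
class OverlapResult:
    """Intersection of two identifier lists; percentages use list A's size."""

    size_a: int
    size_b: int
    shared: int
    shared_ids: list[str]

    @property
    def percent_of_a(self) -> float:
        """Full-precision percentage of list A found in list B."""
        return 100.0 * self.shared / self.size_a

    @property
    def percent_display(self) -> float:
        """The percentage rounded to one decimal for reporting."""
        return round(self.percent_of_a, 1)

    def summary(self, label_a: str = "list A", label_b: str = "list B") -> str:
        return (
            f"{self.shared} of {self.size_a} {label_a} identifiers shared with "
            f"{label_b} ({self.size_b} identifiers): {self.percent_display}% of {label_a}"
        )


def _normalized_unique(ids: Iterable[str], label: str) -> list[str]:
    seen: dict[str, None] = {}
    n_raw = 0
    for raw in ids:
        n_raw += 1
        seen.setdefault(normalize_identifier(raw), None)
    if n_raw == 0:
        raise InputError(f"{label} is empty")
    if len(seen) < n_raw:
        logger.warning(
            "%s: collapsed %d duplicate identifier(s)", label, n_raw - len(seen)
        )
    return list(seen)


def overlap_stats(list_a: Iterable[str], list_b: Iterable[str]) -> OverlapResult:
    """Exact set intersection of two identifier lists.

    Identifiers are normalized (trimmed, casefolded) and duplicates within a
    list collapsed with a logged warning. ``percent_of_a`` uses list A as
    the denominator, so the two argument orders report different percentages
    of the same shared count.
    """
    a = _normalized_unique(list_a, "list A")
    b = _normalized_unique(list_b, "list B")
    b_set = set(b)
    shared_ids = [i for i in a if i in b_set]
    return OverlapResult(
        size_a=len(a), size_b=len(b), shared=len(shared_ids), shared_ids=shared_ids
    )


def tag_ribosomal(
    ids: Iterable[str], prefixes: Sequence[str] = DEFAULT_RP_PREFIXES
) -> tuple[list[str], int]:
    """Identifiers matching ribosomal-protein nomenclature, with their count.

    Matching is a case-insensitive prefix test against ``prefixes``
    (defaults cover cytosolic Rpl/Rps and mitochondrial Mrpl/Mrps symbols).
    Input order is preserved; an empty result is not an error.
    """
    prefs = tuple(p.casefold() for p in prefixes)
    tagged = [
        norm
        for norm in (normalize_identifier(i) for i in ids)
        if norm.startswith(prefs)
    ]
    return tagged, len(tagged)


def hypergeometric_overlap_p(
    size_a: int, size_b: int, shared: int, universe: int
) -> float:
    """Upper-tail P(X >= shared) for the overlap of two lists.

    X follows a hypergeometric law: drawing ``size_a`` genes from a universe
    of ``universe`` in which ``size_b`` are marked. The universe size must be
    supplied by the caller — there is no defensible default.
    """
    if min(size_a, size_b, shared, universe) < 0:
        raise ParameterError("all counts must be nonnegative")
    if shared > min(size_a, size_b):
        raise ParameterError(
            f"shared={shared} exceeds min(size_a, size_b)={min(size_a, size_b)}"
        )
    if max(size_a, size_b) > universe:
        raise ParameterError(
            f"list sizes ({size_a}, {size_b}) exceed universe={universe}"
        )
    return float(stats.hypergeom.sf(shared - 1, universe, size_b, size_a))


def read_id_list(path: str | Path) -> list[str]:
    """Read a plain-text identifier list, one per line; blank lines skipped."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    ids = [ln for ln in lines if ln]
    if not ids:
        raise InputError(f"{path}: no identifiers found")
    return ids
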