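"""bladj-style node-age interpolation and age→branch-length conversion.

Given a tree whose root (and possibly some internal nodes and tips) has a
known age, every uncalibrated node is assigned an age so that branching
events are evenly spaced along the chain between its nearest fixed ancestor
and its best fixed descendant, after which branch lengths are simply
``parent age − child age``. This is the branch-length adjustment popularized
by Phylocom's ``bladj``: it uses no character data, only calibrations and
node counts.

Interpolation rule (made explicit here because "evenly spaced" admits
variants): nodes are visited root-ward first (preorder); a node, once dated,
is treated as fixed for the nodes below it. For an undated node *v* with
nearest fixed ancestor of age ``a_top`` at ``k_top`` edges above, choose
among the fixed descendants reachable through undated nodes the one with the
most intervening (undated) nodes — ties broken by the larger descendant age —
giving ``a_bot`` at ``k_bot`` edges below; then

    age(v) = a_top − (a_top − a_bot) · k_top / (k_top + k_bot)

On a clean chain between two calibrated nodes this spaces the intermediate
ages exactly evenly. The computed age is clamped to be no younger than the
oldest fixed descendant anywhere below *v* (pathological calibration sets can
otherwise force a negative branch); collisions yield zero-length branches and
a warning.

Tips default to age ``default_tip_age`` (0 = extant) unless calibrated
explicitly, so fossil tips may be given positive ages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from .errors import CalibrationError, FormatError
from .trees import Node, Tree

__all__ = ["CalibrationSet", "bladj", "read_calibrations"]


@dataclass
class CalibrationSet:
    """Fixed node ages keyed by node label; root-ward ages are larger."""
    ages: dict[str, float] = field(default_factory=dict)
    default_tip_age: float = 0.0

    def __post_init__(self):
        for label, age in self.ages.items():
            if not (age >= 0 and age == age and age != float("inf")):
                raise CalibrationError(
                    f"age for {label!r} must be finite and >= 0, got {age!r}")


def read_calibrations(text: str, default_tip_age: float = 0.0) -> CalibrationSet:
    """Parse a two-column ``label<TAB>age`` calibration file (``#`` comments
    and blank lines ignored; any run of whitespace separates the columns)."""
    ages: dict[str, float] = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"calibration line {ln}: expected 'label age', "
                              f"got {line!r}")
        label, raw = parts
        try:
            ages[label] = float(raw)
        except ValueError:
            raise FormatError(f"calibration line {ln}: bad age {raw!r}") from None
    return CalibrationSet(ages=ages, default_tip_age=default_tip_age)


def bladj(tree: Tree, calib: CalibrationSet) -> Tree:
    """Return a copy of ``tree`` with every node age set and branch lengths
    equal to the parent/child age difference.

    The root age must be calibrated; a calibrated descendant older than a
    calibrated ancestor is an error. Calibrated nodes keep their exact ages
    (bladj is idempotent: rerunning it on its own output changes nothing).
    """
    work = tree.copy()

    fixed: dict[int, float] = {}  # node id -> fixed age

    def fixed_age(node: Node) -> Optional[float]:
        if node.label is not None and node.label in calib.ages:
            return calib.ages[node.label]
        if node.is_tip:
            return calib.default_tip_age
        return None

    for node in work.preorder():
        a = fixed_age(node)
        if a is not None:
            fixed[node.id] = a
    if work.root.id not in fixed:
        raise CalibrationError(
            "root age is not calibrated (and the root is not a labeled "
            "entry in the calibration set)")

    # consistency: no fixed node older than a fixed ancestor
    for node in work.preorder():
        if node.id not in fixed or node.is_root:
            continue
        anc = node.parent
        while anc is not None:
            if anc.id in fixed:
                if fixed[node.id] > fixed[anc.id] + 1e-12:
                    raise CalibrationError(
                        f"calibration inversion: {node.label!r} "
                        f"(age {fixed[node.id]}) is older than its ancestor "
                        f"{anc.label or 'node ' + str(anc.id)!r} "
                        f"(age {fixed[anc.id]})")
                break
            anc = anc.parent

    ages: dict[int, float] = dict(fixed)
    collisions: list[str] = []

    def best_fixed_descendant(v: Node) -> tuple[float, int]:
        """(age, edge count) of the fixed descendant with the most intervening
        undated nodes below v; ties -> larger age."""
        best = None  # (intervening, age, k)
        stack = [(c, 1) for c in v.children]
        while stack:
            node, k = stack.pop()
            if node.id in ages:
                cand = (k - 1, ages[node.id], k)
                if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                    best = cand
            else:
                stack.extend((c, k + 1) for c in node.children)
        assert best is not None  # every tip is fixed, so always reachable
        return best[1], best[2]

    def max_fixed_below(v: Node) -> float:
        out = -float("inf")
        stack = list(v.children)
        while stack:
            node = stack.pop()
            if node.id in ages:
                out = max(out, ages[node.id])
            else:
                stack.extend(node.children)
        return out

    # preorder guarantees every ancestor is dated before its descendants,
    # so the nearest fixed ancestor is just the parent
    for node in work.preorder():
        if node.id in ages:
            continue
        a_top = ages[node.parent.id]
        k_top = 1
        a_bot, k_bot = best_fixed_descendant(node)
        age = a_top - (a_top - a_bot) * k_top / (k_top + k_bot)
        floor = max_fixed_below(node)
        if age < floor:
            age = floor
        if age == a_top or age == floor == a_bot:
            collisions.append(node.label or f"node {node.id}")
        ages[node.id] = age

    for node in work.preorder():
        node.age = ages[node.id]
        if node.is_root:
            node.branch_length = None
        else:
            bl = ages[node.parent.id] - ages[node.id]
            if bl < 0:
                # cannot happen after clamping; keep the guard explicit
                raise CalibrationError(
                    f"negative branch above {node.label or node.id}")
            node.branch_length = bl

    if collisions:
        warnings.warn(
            "bladj produced zero-length branches at: " + ", ".join(collisions),
            stacklevel=2)
    return work
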