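"""Yield model for multi-subunit protein-complex assembly pathways.

The model quantifies how failures at intermediate assembly steps accumulate
as a complex of n subunits is built along a binary assembly tree, and how
co-translational capture of a subunit improves the outcome.  Two failure
modes compete with productive assembly:

* **Specificity competition.**  Each join succeeds with probability
  ``s`` in (0, 1], the odds of the specific interaction winning against the
  pool of promiscuous competitors.  Co-translational capture holds the
  partner at the ribosome, increasing the dwell-time of the nascent
  interface by a factor ``delta >= 1`` and shifting the kinetic competition
  to ``s_eff = s * delta / (s * delta + (1 - s))``.
* **Orphan-intermediate hazard.**  Every part (subunit or partial complex)
  waiting for its next partner is an orphan exposed to misassembly or
  aggregation at rate ``lambda`` per unit time.  A part born at time t_u and
  joined at time t_join survives with probability exp(-lambda * a_u),
  a_u = t_join - t_u.

Joins are scheduled level-synchronously: a join fires one waiting time
``tau`` after both of its inputs exist (the diffusive default), or ``tau_tr``
— the translation-limited wait — for co-translational joins, whose captured
leaf additionally accrues no orphan exposure.  The closed-form yield is

    Y = prod_joins s_eff  *  exp(-lambda * sum_parts a_u),

which for a sequential chain with lambda = 0 reduces to Y = s**(n-1): the
yield decays exponentially with the number of subunits.  Hierarchical
(balanced) trees shorten every lineage and strictly reduce the total orphan
exposure, so balanced >= sequential whenever lambda > 0.

A seeded Monte-Carlo simulator serves as an independent stochastic oracle;
in deterministic-wait mode it draws from exactly the model the closed form
integrates, in exponential-wait mode the waits are Exp(tau) distributed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml


# ---------------------------------------------------------------------------
# Tree plumbing


@dataclass
class _Node:
    """Internal binary-tree node; leaves carry a name, joins carry children."""

    name: str | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None
    cotranslational: bool = False  # set on join nodes

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self) -> list["_Node"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def postorder(self) -> list["_Node"]:
        if self.is_leaf:
            return [self]
        return self.left.postorder() + self.right.postorder() + [self]


def _build(tree) -> _Node:
    if isinstance(tree, str):
        return _Node(name=tree)
    if isinstance(tree, (list, tuple)) and len(tree) == 2:
        return _Node(left=_build(tree[0]), right=_build(tree[1]))
    if isinstance(tree, (list, tuple)) and len(tree) == 1:
        return _build(tree[0])
    raise ValueError(f"tree nodes must be leaf names or pairs, got {tree!r}")


def sequential_tree(n: int) -> list | str:
    """Chain topology: ((((S1, S2), S3), S4), ...)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    tree: list | str = "S1"
    for i in range(2, n + 1):
        tree = [tree, f"S{i}"]
    return tree


def balanced_tree(n: int) -> list | str:
    """Balanced topology: recursively halve the subunit list."""
    if n < 1:
        raise ValueError("n must be >= 1")

    def rec(names: list[str]):
        if len(names) == 1:
            return names[0]
        k = len(names) // 2
        return [rec(names[:k]), rec(names[k:])]

    return rec([f"S{i}" for i in range(1, n + 1)])


# ---------------------------------------------------------------------------
# Pathway model


@dataclass
class YieldResult:
    """Expected assembly yield and its decomposition.

    ``specificity_component`` is the product of per-join success odds,
    ``hazard_component`` is exp(-lambda * total_exposure); the closed-form
    yield is their product.  Monte-Carlo estimates additionally carry the
    trial count, success count and binomial standard error.
    """

    yield_: float
    specificity_component: float
    hazard_component: float
    total_exposure: float
    exposures: dict[str, float] = field(default_factory=dict)
    n_trials: int | None = None
    successes: int | None = None
    se: float | None = None

    def summary(self) -> str:
        lines = [
            f"assembly yield Y = {self.yield_:.6g}",
            f"  specificity component: {self.specificity_component:.6g}",
            f"  hazard component:      {self.hazard_component:.6g}",
            f"  total orphan exposure: {self.total_exposure:.6g} time units",
        ]
        if self.n_trials is not None:
            lines.append(
                f"  Monte-Carlo: {self.successes}/{self.n_trials} trials, SE {self.se:.3g}"
            )
        return "\n".join(lines)


class AssemblyPathway:
    """A binary assembly tree with kinetic parameters.

    Parameters
    ----------
    tree : nested lists/strings
        Binary topology over subunit names, e.g. ``[["A", "B"], ["C", "D"]]``.
    specificity : float in (0, 1]
        Per-join probability that the specific interaction outcompetes
        promiscuous binders.
    hazard : float >= 0
        Orphan loss rate lambda per unit time.
    wait : float >= 0
        Diffusive waiting time tau per join.
    cotranslational : iterable of leaf names
        Leaves captured co-translationally at their parent join: the join's
        wait becomes ``translation_wait``, its success odds use the dwell
        factor, and the captured leaf accrues no orphan exposure.
    dwell_factor : float >= 1
        Dwell-time multiplier delta for co-translational joins.
    translation_wait : float >= 0
        Wait tau_tr for co-translational joins (defaults to ``wait``).
    """

    def __init__(
        self,
        tree,
        specificity: float = 0.95,
        hazard: float = 0.0,
        wait: float = 1.0,
        cotranslational: Sequence[str] = (),
        dwell_factor: float = 1.0,
        translation_wait: float | None = None,
    ):
        self.root = _build(tree)
        leaves = self.root.leaves()
        names = [lf.name for lf in leaves]
        if len(set(names)) != len(names):
            raise ValueError("subunit names must be unique")
        if not 0 < specificity <= 1:
            raise ValueError("specificity must be in (0, 1]")
        if hazard < 0:
            raise ValueError("hazard rate must be >= 0")
        if wait < 0:
            raise ValueError("waiting time must be >= 0")
        if dwell_factor < 1:
            raise ValueError("dwell factor must be >= 1")
        if translation_wait is not None and translation_wait < 0:
            raise ValueError("translation_wait must be >= 0")

        self.specificity = float(specificity)
        self.hazard = float(hazard)
        self.wait = float(wait)
        self.dwell_factor = float(dwell_factor)
        self.translation_wait = float(wait if translation_wait is None else translation_wait)
        self.cotranslational = set(cotranslational)
        unknown = self.cotranslational - set(names)
        if unknown:
            raise ValueError(f"co-translational flags for unknown subunits: {sorted(unknown)}")

        # a join is co-translational when it captures a flagged leaf child
        self._captured: set[int] = set()  # ids of captured leaf nodes
        for node in self.root.postorder():
            if node.is_leaf:
                continue
            for child in (node.left, node.right):
                if child.is_leaf and child.name in self.cotranslational:
                    node.cotranslational = True
                    self._captured.add(id(child))
        flagged_parents = {
            lf.name
            for node in self.root.postorder()
            if not node.is_leaf and node.cotranslational
            for lf in (node.left, node.right)
            if lf.is_leaf and lf.name in self.cotranslational
        }
        missing = self.cotranslational - flagged_parents
        if missing:  # flagged leaf that is not a direct child of any join — impossible by construction
            raise ValueError(f"could not attach co-translational flags: {sorted(missing)}")

    # -- basic properties ---------------------------------------------------

    @property
    def n_subunits(self) -> int:
        return len(self.root.leaves())

    @property
    def n_joins(self) -> int:
        return self.n_subunits - 1

    @property
    def s_eff_cotranslational(self) -> float:
        s, d = self.specificity, self.dwell_factor
        return s * d / (s * d + (1 - s))

    def _node_label(self, node: _Node) -> str:
        if node.is_leaf:
            return node.name
        return "(" + "+".join(lf.name for lf in node.leaves()) + ")"

    # -- constructors -------------------------------------------------------

    @classmethod
    def sequential(cls, n: int, **kw) -> "AssemblyPathway":
        return cls(sequential_tree(n), **kw)

    @classmethod
    def balanced(cls, n: int, **kw) -> "AssemblyPathway":
        return cls(balanced_tree(n), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "AssemblyPathway":
        return cls(
            d["tree"],
            specificity=d.get("specificity", 0.95),
            hazard=d.get("hazard", 0.0),
            wait=d.get("wait", 1.0),
            cotranslational=d.get("cotranslational", ()),
            dwell_factor=d.get("dwell_factor", 1.0),
            translation_wait=d.get("translation_wait"),
        )

    @classmethod
    def from_yaml(cls, path) -> "AssemblyPathway":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- closed form --------------------------------------------------------

    def _join_times(self) -> dict[int, float]:
        """Deterministic level-synchronous join times: t = max(children) + wait."""
        times: dict[int, float] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                times[id(node)] = 0.0
            else:
                w = self.translation_wait if node.cotranslational else self.wait
                times[id(node)] = max(times[id(node.left)], times[id(node.right)]) + w
        return times

    def _exposures(self, times: dict[int, float]) -> dict[str, float]:
        """Per-part orphan exposure: birth to joining; captured leaves accrue none."""
        out: dict[str, float] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                continue
            for child in (node.left, node.right):
                if id(child) in self._captured:
                    a = 0.0
                else:
                    a = times[id(node)] - times[id(child)]
                out[self._node_label(child)] = a
        return out

    def closed_form_yield(self) -> YieldResult:
        """Exact expected yield under deterministic waits."""
        times = self._join_times()
        exposures = self._exposures(times)
        total_exposure = sum(exposures.values())
        spec = 1.0
        for node in self.root.postorder():
            if node.is_leaf:
                continue
            spec *= self.s_eff_cotranslational if node.cotranslational else self.specificity
        hazard_comp = math.exp(-self.hazard * total_exposure)
        return YieldResult(
            yield_=spec * hazard_comp,
            specificity_component=spec,
            hazard_component=hazard_comp,
            total_exposure=total_exposure,
            exposures=exposures,
        )

    # -- Monte-Carlo --------------------------------------------------------

    def simulate(
        self, n_trials: int = 20_000, seed: int = 0, waits: str = "deterministic"
    ) -> YieldResult:
        """Monte-Carlo yield estimate.

        ``waits = "deterministic"`` reproduces exactly the process the closed
        form integrates (join waits fixed at tau / tau_tr); ``"exponential"``
        draws diffusive waits from Exp(mean tau) while co-translational joins
        keep the fixed translation-limited wait tau_tr.
        """
        if n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if waits not in ("deterministic", "exponential"):
            raise ValueError("waits must be 'deterministic' or 'exponential'")
        rng = np.random.default_rng(seed)
        nodes = self.root.postorder()
        times: dict[int, np.ndarray] = {}
        success = np.ones(n_trials, dtype=bool)
        total_exposure = np.zeros(n_trials)
        for node in nodes:
            if node.is_leaf:
                times[id(node)] = np.zeros(n_trials)
                continue
            if node.cotranslational:
                w = np.full(n_trials, self.translation_wait)
                s_join = self.s_eff_cotranslational
            elif waits == "exponential":
                w = rng.exponential(self.wait, n_trials) if self.wait > 0 else np.zeros(n_trials)
                s_join = self.specificity
            else:
                w = np.full(n_trials, self.wait)
                s_join = self.specificity
            t_join = np.maximum(times[id(node.left)], times[id(node.right)]) + w
            times[id(node)] = t_join
            # specificity competition at this join
            success &= rng.random(n_trials) < s_join
            # orphan hazard on both inputs while they waited
            for child in (node.left, node.right):
                if id(child) in self._captured:
                    continue
                a = t_join - times[id(child)]
                total_exposure += a
                if self.hazard > 0:
                    success &= rng.random(n_trials) < np.exp(-self.hazard * a)
        n_succ = int(success.sum())
        p_hat = n_succ / n_trials
        se = math.sqrt(p_hat * (1 - p_hat) / n_trials)
        cf = self.closed_form_yield()
        return YieldResult(
            yield_=p_hat,
            specificity_component=cf.specificity_component,
            hazard_component=cf.hazard_component,
            total_exposure=float(total_exposure.mean()),
            exposures={},
            n_trials=n_trials,
            successes=n_succ,
            se=se,
        )


def simulate_assembly(pathway: AssemblyPathway, n_trials: int = 20_000, seed: int = 0, waits: str = "deterministic") -> YieldResult:
    """Functional alias for :meth:`AssemblyPathway.simulate`."""
    return pathway.simulate(n_trials=n_trials, seed=seed, waits=waits)


def closed_form_yield(pathway: AssemblyPathway) -> YieldResult:
    """Functional alias for :meth:`AssemblyPathway.closed_form_yield`."""
    return pathway.closed_form_yield()


# ---------------------------------------------------------------------------
# Yield-vs-n curves and pathway comparison


def yield_vs_n(
    specificity: float,
    hazard: float,
    wait: float,
    topology: str = "sequential",
    n_range: Sequence[int] = range(1, 17),
    **kw,
) -> dict:
    """Closed-form Y(n) over a range of subunit counts.

    Returns a dict with ``n``, ``yield`` arrays and — for the sequential
    topology — the fitted slope of log Y vs n (equals log s when lambda = 0).
    """
    n_range = list(n_range)
    if any(n < 1 or n > 64 for n in n_range):
        raise ValueError("subunit counts must lie in [1, 64]")
    maker = {"sequential": AssemblyPathway.sequential, "balanced": AssemblyPathway.balanced}
    if topology not in maker:
        raise ValueError(f"unknown topology {topology!r}")
    ys = []
    for n in n_range:
        if n == 1:
            ys.append(1.0)
            continue
        pw = maker[topology](n, specificity=specificity, hazard=hazard, wait=wait, **kw)
        ys.append(pw.closed_form_yield().yield_)
    out = {"n": np.array(n_range), "yield": np.array(ys), "topology": topology}
    if topology == "sequential" and len(n_range) >= 2:
        slope = np.polyfit(out["n"], np.log(out["yield"]), 1)[0]
        out["log_yield_slope"] = float(slope)
    return out


@dataclass
class PathwayComparison:
    yield_a: float
    yield_b: float
    ratio: float
    specificity_a: float
    specificity_b: float
    hazard_a: float
    hazard_b: float
    differing_component: str

    def summary(self) -> str:
        return (
            f"Y_a = {self.yield_a:.6g}, Y_b = {self.yield_b:.6g}, "
            f"ratio a/b = {self.ratio:.4g} (differs in: {self.differing_component})"
        )


def compare_pathways(a: AssemblyPathway, b: AssemblyPathway) -> PathwayComparison:
    """Compare closed-form yields of two pathways over the same subunit count."""
    if a.n_subunits != b.n_subunits:
        raise ValueError(
            f"pathways assemble different subunit counts ({a.n_subunits} vs {b.n_subunits})"
        )
    ra, rb = a.closed_form_yield(), b.closed_form_yield()
    diff = []
    if not math.isclose(ra.specificity_component, rb.specificity_component, rel_tol=1e-12):
        diff.append("specificity")
    if not math.isclose(ra.hazard_component, rb.hazard_component, rel_tol=1e-12):
        diff.append("hazard")
    return PathwayComparison(
        yield_a=ra.yield_,
        yield_b=rb.yield_,
        ratio=ra.yield_ / rb.yield_ if rb.yield_ > 0 else math.inf,
        specificity_a=ra.specificity_component,
        specificity_b=rb.specificity_component,
        hazard_a=ra.hazard_component,
        hazard_b=rb.hazard_component,
        differing_component=" & ".join(diff) if diff else "none",
    )


def result_to_json(result: YieldResult) -> str:
    d = {
        "yield": result.yield_,
        "specificity_component": result.specificity_component,
        "hazard_component": result.hazard_component,
        "total_exposure": result.total_exposure,
        "exposures": result.exposures,
    }
    if result.n_trials is not None:
        d.update(n_trials=result.n_trials, successes=result.successes, se=result.se)
    return json.dumps(d, indent=2)
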