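"""Recursive path-model specification, estimation, and pruning.

A recursive path model is an observed-variable structural equation system
whose directed edges form a DAG; it is estimable equation by equation.
Each endogenous variable is regressed on its parents by ordinary least
squares on z-scored data, yielding standardized path coefficients (SC)
with normal-reference inference (z = SC/SE, two-sided P, 95% CI as
SC +/- 1.96*SE) and a residual variance proportion epsilon = 1 - R^2.

Two builders return the published model structures: the hypothetical
model (every histology grade feeding every clinical/treatment mediator
and the eGFR-slope outcome) and the final pruned model whose 20 directed
edges carry the published standardized coefficients.

Correlational links (e.g. between baseline proteinuria and baseline eGFR)
are operationalized as a regression term inside a designated host
equation; their non-traversable flag excludes them from effect
decomposition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "Edge",
    "CorrLink",
    "PathModelSpec",
    "EquationFit",
    "PathFitResult",
    "SingularDesignError",
    "hypothetical_spec",
    "final_spec",
    "fit",
    "prune",
    "parse_model",
    "to_model_syntax",
    "PUBLISHED_COEFFICIENTS",
    "PUBLISHED_RESIDUAL_PROPORTIONS",
]

HISTOLOGY = ["M", "E", "S", "T", "C"]
CLINICAL = ["UPE0c", "SReGFR0c", "MAPc01"]
TREATMENT = ["ST", "RASB"]
OUTCOME = "SLOPE"

#: Published standardized path coefficients of the final model
#: (20 directed/correlational regression terms), keyed (parent, child).
PUBLISHED_COEFFICIENTS: Dict[Tuple[str, str], float] = {
    ("UPE0c", "SLOPE"): -0.073,
    ("SReGFR0c", "SLOPE"): -0.224,
    ("ST", "SLOPE"): 0.127,
    ("T", "SLOPE"): -0.095,
    ("SReGFR0c", "UPE0c"): -0.205,
    ("M", "UPE0c"): 0.194,
    ("C", "UPE0c"): 0.102,
    ("S", "MAPc01"): 0.091,
    ("T", "MAPc01"): 0.237,
    ("S", "SReGFR0c"): -0.095,
    ("T", "SReGFR0c"): -0.545,
    ("UPE0c", "ST"): 0.108,
    ("MAPc01", "ST"): -0.069,
    ("SReGFR0c", "ST"): 0.109,
    ("S", "ST"): 0.127,
    ("E", "ST"): 0.114,
    ("C", "ST"): 0.180,
    ("UPE0c", "RASB"): 0.088,
    ("MAPc01", "RASB"): 0.207,
    ("SReGFR0c", "RASB"): -0.300,
}

#: Published residual variance proportions (error terms) per endogenous variable.
PUBLISHED_RESIDUAL_PROPORTIONS: Dict[str, float] = {
    "MAPc01": 0.93,
    "SReGFR0c": 0.68,
    "UPE0c": 0.89,
    "ST": 0.88,
    "RASB": 0.83,
    "SLOPE": 0.95,
}


class SingularDesignError(ValueError):
    """Collinear or zero-variance design in one equation."""


@dataclass(frozen=True)
class Edge:
    parent: str
    child: str
    traversable: bool = True


@dataclass(frozen=True)
class CorrLink:
    """Correlational link between two variables, estimated as a regression
    term inside ``host``'s equation but never traversed in decomposition."""
    a: str
    b: str
    host: str


@dataclass
class PathModelSpec:
    """DAG of directed edges plus correlational links among named variables."""

    nodes: Dict[str, str]                 # name -> "exogenous" | "endogenous"
    directed_edges: List[Edge] = field(default_factory=list)
    correlational_links: List[CorrLink] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("directed edges must form a DAG")
        for e in self.directed_edges:
            if e.parent not in self.nodes or e.child not in self.nodes:
                raise ValueError(f"edge {e.parent}->{e.child} names unknown node")
        if OUTCOME in self.nodes and any(
                e.parent == OUTCOME for e in self.directed_edges):
            raise ValueError(f"{OUTCOME} must have no outgoing edges")
        for link in self.correlational_links:
            if link.host not in (link.a, link.b):
                raise ValueError(
                    f"correlational link {link.a}~~{link.b} host must be one "
                    "of its endpoints")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.parent, e.child) for e in self.directed_edges)
        return g

    def endogenous(self) -> List[str]:
        order = list(nx.topological_sort(self.graph()))
        return [v for v in order if self.nodes[v] == "endogenous"]

    def exogenous(self) -> List[str]:
        return [v for v in self.nodes if self.nodes[v] == "exogenous"]

    def equation_terms(self, child: str) -> List[str]:
        """Regressors of ``child``: directed parents plus hosted correlational
        partners, in stable order."""
        terms = [e.parent for e in self.directed_edges if e.child == child]
        for link in self.correlational_links:
            if link.host == child:
                other = link.b if link.host == link.a else link.a
                terms.append(other)
        return terms

    def traversable_children(self, node: str) -> List[str]:
        return sorted(e.child for e in self.directed_edges
                      if e.parent == node and e.traversable)

    def edge_set(self) -> set:
        """Hashable summary of the surviving structure (for pruning checks)."""
        return ({(e.parent, e.child) for e in self.directed_edges}
                | {("~~",) + tuple(sorted((l.a, l.b)))
                   for l in self.correlational_links})


def _all_nodes() -> Dict[str, str]:
    nodes = {v: "exogenous" for v in HISTOLOGY}
    nodes.update({v: "endogenous" for v in CLINICAL + TREATMENT + [OUTCOME]})
    return nodes


def hypothetical_spec() -> PathModelSpec:
    """The full starting model.

    Every histology indicator points at every clinical variable, both
    treatment variables, and the outcome; every clinical variable points at
    both treatments and the outcome; both treatments point at the outcome.
    Correlational links UPE0c~~SReGFR0c and UPE0c~~MAPc01 are hosted in the
    UPE0c equation and are non-traversable.
    """
    edges = []
    for h in HISTOLOGY:
        for child in CLINICAL + TREATMENT + [OUTCOME]:
            edges.append(Edge(h, child))
    for c in CLINICAL:
        for child in TREATMENT + [OUTCOME]:
            edges.append(Edge(c, child))
    for t in TREATMENT:
        edges.append(Edge(t, OUTCOME))
    links = [CorrLink("UPE0c", "SReGFR0c", host="UPE0c"),
             CorrLink("UPE0c", "MAPc01", host="UPE0c")]
    # hosted correlational terms replace the directed histology-independent
    # clinical->UPE0c edges that would duplicate them
    edges = [e for e in edges
             if not (e.child == "UPE0c" and e.parent in ("SReGFR0c", "MAPc01"))]
    return PathModelSpec(nodes=_all_nodes(), directed_edges=edges,
                         correlational_links=links)


def final_spec() -> PathModelSpec:
    """The published pruned model (20 coefficient rows).

    Directed:  MAPc01 ~ S + T;  SReGFR0c ~ S + T;  UPE0c ~ M + C;
    ST ~ UPE0c + MAPc01 + SReGFR0c + S + E + C;
    RASB ~ UPE0c + MAPc01 + SReGFR0c;  SLOPE ~ UPE0c + SReGFR0c + ST + T.
    Correlational: UPE0c ~~ SReGFR0c hosted in the UPE0c equation,
    non-traversable.  RASB keeps its equation although it has no route to
    the outcome.
    """
    edges = [
        Edge("M", "UPE0c"), Edge("C", "UPE0c"),
        Edge("S", "MAPc01"), Edge("T", "MAPc01"),
        Edge("S", "SReGFR0c"), Edge("T", "SReGFR0c"),
        Edge("UPE0c", "ST"), Edge("MAPc01", "ST"), Edge("SReGFR0c", "ST"),
        Edge("S", "ST"), Edge("E", "ST"), Edge("C", "ST"),
        Edge("UPE0c", "RASB"), Edge("MAPc01", "RASB"), Edge("SReGFR0c", "RASB"),
        Edge("UPE0c", "SLOPE"), Edge("SReGFR0c", "SLOPE"),
        Edge("ST", "SLOPE"), Edge("T", "SLOPE"),
    ]
    links = [CorrLink("UPE0c", "SReGFR0c", host="UPE0c")]
    return PathModelSpec(nodes=_all_nodes(), directed_edges=edges,
                         correlational_links=links)


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

@dataclass
class CoefficientEstimate:
    sc: float       # standardized coefficient
    se: float
    z: float
    p: float        # two-sided, normal reference
    ci_low: float
    ci_high: float


@dataclass
class EquationFit:
    child: str
    coefficients: Dict[str, CoefficientEstimate]
    intercept: float        # on the pre-standardization scale (_cons)
    r_squared: float

    @property
    def epsilon(self) -> float:
        """Residual variance proportion 1 - R^2 of this equation."""
        return 1.0 - self.r_squared


@dataclass
class PathFitResult:
    equations: Dict[str, EquationFit]
    n: int
    correlation: pd.DataFrame   # sample correlation matrix of all model variables
    covariance: pd.DataFrame    # sample covariance matrix (ddof=1)

    def coefficient_map(self) -> Dict[Tuple[str, str], float]:
        return {(parent, eq.child): est.sc
                for eq in self.equations.values()
                for parent, est in eq.coefficients.items()}

    def p_value(self, parent: str, child: str) -> float:
        return self.equations[child].coefficients[parent].p

    def to_frame(self) -> pd.DataFrame:
        """Long-format coefficient table (one row per equation term)."""
        rows = []
        for child, eq in self.equations.items():
            for parent, est in eq.coefficients.items():
                rows.append({
                    "equation": child, "term": parent, "SC": est.sc,
                    "SE": est.se, "z": est.z, "P": est.p,
                    "CI_low": est.ci_low, "CI_high": est.ci_high,
                })
            rows.append({"equation": child, "term": "_cons",
                         "SC": eq.intercept, "SE": np.nan, "z": np.nan,
                         "P": np.nan, "CI_low": np.nan, "CI_high": np.nan})
        return pd.DataFrame(rows)


_CONDITION_LIMIT = 1e8


def fit(spec: PathModelSpec, table, allow_small_sample: bool = True) -> PathFitResult:
    """Fit each endogenous equation by OLS on z-scored data.

    ``table`` is a :class:`~iganpath.cohort.CohortTable` or a DataFrame
    containing every model variable.  Variables (including binary
    indicators) are z-scored with the sample standard deviation (ddof=1);
    intercepts are estimated on the raw scale and reported separately.
    """
    df = table.data if hasattr(table, "data") else table
    names = list(spec.nodes)
    missing = [v for v in names if v not in df.columns]
    if missing:
        raise ValueError(f"table lacks model variables: {missing}")
    data = df[names].astype(float)
    sd = data.std(ddof=1)
    if (sd <= 0).any():
        bad = list(sd.index[sd <= 0])
        raise SingularDesignError(f"zero-variance variables: {bad}")
    z = (data - data.mean()) / sd

    equations = {}
    for child in spec.endogenous():
        terms = spec.equation_terms(child)
        if len(data) <= len(terms) + 1:
            raise ValueError(
                f"equation {child}: n={len(data)} too small for "
                f"{len(terms)} parents")
        X = sm.add_constant(z[terms].to_numpy())
        if np.linalg.cond(X) > _CONDITION_LIMIT:
            raise SingularDesignError(
                f"equation {child}: collinear parents {terms}")
        res = sm.OLS(z[child].to_numpy(), X).fit()
        coeffs = {}
        for j, parent in enumerate(terms, start=1):
            sc = float(res.params[j])
            se = float(res.bse[j])
            zstat = sc / se
            coeffs[parent] = CoefficientEstimate(
                sc=sc, se=se, z=zstat,
                p=float(2.0 * stats.norm.sf(abs(zstat))),
                ci_low=sc - 1.96 * se, ci_high=sc + 1.96 * se)
        raw = sm.OLS(data[child].to_numpy(),
                     sm.add_constant(data[terms].to_numpy())).fit()
        equations[child] = EquationFit(
            child=child, coefficients=coeffs,
            intercept=float(raw.params[0]),
            r_squared=float(res.rsquared))

    return PathFitResult(
        equations=equations, n=len(data),
        correlation=data.corr(), covariance=data.cov())


def prune(
    spec: PathModelSpec,
    fitresult: PathFitResult,
    alpha: float = 0.1,
) -> Tuple[PathModelSpec, bool]:
    """Remove every directed edge and correlational link with P >= alpha.

    All nodes are retained: a node losing its route to the outcome keeps
    its own equation.  The returned flag is True when the surviving
    structure is identical at thresholds 0.05 and 0.1 (no elimination
    bias).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")

    def survives(threshold):
        edges = [e for e in spec.directed_edges
                 if fitresult.p_value(e.parent, e.child) < threshold]
        links = []
        for link in spec.correlational_links:
            other = link.b if link.host == link.a else link.a
            if fitresult.p_value(other, link.host) < threshold:
                links.append(link)
        return edges, links

    edges, links = survives(alpha)
    pruned = PathModelSpec(nodes=dict(spec.nodes), directed_edges=edges,
                           correlational_links=links)
    e05, l05 = survives(0.05)
    e10, l10 = survives(0.1)
    bias_free = (
        {(e.parent, e.child) for e in e05} == {(e.parent, e.child) for e in e10}
        and set(l05) == set(l10))
    return pruned, bias_free


# ---------------------------------------------------------------------------
# Declarative model syntax
# ---------------------------------------------------------------------------
#
# One line per equation:        child ~ parent1 + parent2
# Correlational link:           a ~~ b @host=a
# Exogenous variables are those never appearing on a left-hand side.

_EQ_RE = re.compile(r"^(\w+)\s*~\s*(?!~)(.+)$")
_LINK_RE = re.compile(r"^(\w+)\s*~~\s*(\w+)\s*@host=(\w+)$")


def parse_model(text: str) -> PathModelSpec:
    """Parse the declarative model syntax into a :class:`PathModelSpec`."""
    edges: List[Edge] = []
    links: List[CorrLink] = []
    seen: List[str] = []
    endogenous = set()
    for raw_line in text.splitlines():
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        m = _LINK_RE.match(line)
        if m:
            a, b, host = m.groups()
            links.append(CorrLink(a, b, host=host))
            for v in (a, b):
                if v not in seen:
                    seen.append(v)
            continue
        m = _EQ_RE.match(line)
        if m:
            child, rhs = m.group(1), m.group(2)
            parents = [p.strip() for p in rhs.split("+")]
            endogenous.add(child)
            for v in [child] + parents:
                if v not in seen:
                    seen.append(v)
            edges.extend(Edge(p, child) for p in parents)
            continue
        raise ValueError(f"cannot parse model line: {raw_line!r}")
    endogenous |= {l.host for l in links}
    nodes = {v: ("endogenous" if v in endogenous else "exogenous") for v in seen}
    return PathModelSpec(nodes=nodes, directed_edges=edges,
                         correlational_links=links)


def to_model_syntax(spec: PathModelSpec) -> str:
    """Serialize a spec to the declarative syntax (round-trips parse_model)."""
    lines = []
    for child in spec.endogenous():
        parents = [e.parent for e in spec.directed_edges if e.child == child]
        if parents:
            lines.append(f"{child} ~ " + " + ".join(parents))
    for link in spec.correlational_links:
        lines.append(f"{link.a} ~~ {link.b} @host={link.host}")
    return "\n".join(lines) + "\n"
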