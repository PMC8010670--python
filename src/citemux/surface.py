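"""Surface-protein (ADT) processing: CLR normalization, positivity calls,
multiplet exclusion rules and marker-based cell-type annotation.

ADT counts are compositional within a cell (the antibody pool competes for
the same droplet), so they are normalized with a centered log ratio per
cell: ``clr_pc = ln(x_pc + 1) − mean_p ln(x_pc + 1)``. Each protein's CLR
distribution across cells is bimodal (background staining vs. true
expression); the same two-component Gaussian mixture machinery used for
hashtag demultiplexing converts it into a per-cell positive/negative call.

Cells positive for lineage-incompatible marker combinations (a CD19+ cell
that is also CD3+, say) are physically interacting or co-encapsulated
multiplets; a declarative rule table — anchors plus forbidden marker
groups, one rule per major lineage — flags them for removal. Remaining
cells are annotated by marker precedence (T > monocyte > B > NK), with
CD45RA/CD45RO resolving naive vs. memory T cells and CD69/CD25 marking
activation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .mixture import DegenerateFitError, fit_two_component

log = logging.getLogger(__name__)

CELL_TYPES = ("B", "NK", "CD14_monocyte", "CD4_T", "CD8_T", "unassigned")


@dataclass(frozen=True)
class MultipletRule:
    """All ``anchors`` positive AND >= 1 marker of any forbidden group."""

    rule_id: str
    anchors: tuple[str, ...]
    forbidden: tuple[tuple[str, ...], ...]


@dataclass
class MarkerRuleSet:
    """Multiplet rules plus the annotation marker scheme."""

    rules: tuple[MultipletRule, ...]
    precedence: tuple[dict, ...]
    naive_marker: str = "CD45RA"
    memory_marker: str = "CD45RO"
    activation_markers: tuple[str, ...] = ("CD69", "CD25")

    def validate(self, panel: list[str]) -> None:
        """Error if any rule or annotation marker is absent from the panel."""
        known = set(panel)
        for rule in self.rules:
            used = set(rule.anchors) | {m for g in rule.forbidden for m in g}
            missing = used - known
            if missing:
                raise ValueError(
                    f"rule {rule.rule_id} references unknown marker(s) "
                    f"{sorted(missing)}")
        ann = {self.naive_marker, self.memory_marker,
               *self.activation_markers}
        for step in self.precedence:
            ann |= set(step.get("require_all", []))
            ann |= set(step.get("require_any", []))
        missing = ann - known
        if missing:
            raise ValueError(f"annotation references unknown marker(s) "
                             f"{sorted(missing)}")

    @property
    def rule_markers(self) -> list[str]:
        """Every marker referenced by at least one multiplet rule."""
        out: dict[str, None] = {}
        for rule in self.rules:
            for m in rule.anchors:
                out.setdefault(m)
            for g in rule.forbidden:
                for m in g:
                    out.setdefault(m)
        return list(out)


def load_marker_rules(path: str | Path | None = None) -> MarkerRuleSet:
    """Load the rule table from YAML (bundled default when no path given)."""
    if path is None:
        text = (resources.files("citemux") / "data" / "multiplet_rules.yaml"
                ).read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    rules = tuple(
        MultipletRule(rule_id=r["id"], anchors=tuple(r["anchors"]),
                      forbidden=tuple(tuple(g) for g in r["forbidden"]))
        for r in raw["multiplet_rules"])
    ann = raw["annotation"]
    return MarkerRuleSet(rules=rules,
                         precedence=tuple(ann["precedence"]),
                         naive_marker=ann["naive_marker"],
                         memory_marker=ann["memory_marker"],
                         activation_markers=tuple(ann["activation_markers"]))


def clr_normalize(adt: sp.spmatrix | np.ndarray,
                  pseudocount: float = 1.0) -> np.ndarray:
    """Centered log ratio per cell: ln(x+1) minus the cell's mean ln(x+1)."""
    x = np.asarray(adt.todense() if sp.issparse(adt) else adt, dtype=float)
    logged = np.log(x + pseudocount)
    return logged - logged.mean(axis=0, keepdims=True)


def call_positivity(clr: np.ndarray, seed: int = 0,
                    threshold: float = 0.5) -> np.ndarray:
    """Per-protein positive/negative calls from the CLR matrix.

    Fits a two-component Gaussian mixture per protein (row) across cells;
    positive = posterior of the high-mean component strictly above
    ``threshold`` (a posterior of exactly the threshold is negative). A
    degenerate protein (e.g. constant) yields all-negative with a warning.
    """
    clr = np.asarray(clr, dtype=float)
    positive = np.zeros(clr.shape, dtype=bool)
    for p in range(clr.shape[0]):
        try:
            fit = fit_two_component(clr[p], seed=seed + p)
        except DegenerateFitError as err:
            log.warning("protein row %d: degenerate distribution (%s); "
                        "calling all cells negative", p, err)
            continue
        positive[p] = fit.posterior_positive > threshold
    return positive


def apply_multiplet_rules(positive: np.ndarray, panel: list[str],
                          rules: MarkerRuleSet) -> pd.DataFrame:
    """Flag cells for which any exclusion rule fires.

    Returns per cell: ``multiplet_flag`` and the ``;``-joined ids of every
    rule that fired. Idempotent by construction (pure function of the
    positivity matrix).
    """
    rules.validate(panel)
    idx = {m: i for i, m in enumerate(panel)}
    n_cells = positive.shape[1]
    flagged = np.zeros(n_cells, dtype=bool)
    fired: list[list[str]] = [[] for _ in range(n_cells)]
    for rule in rules.rules:
        anchor_ok = np.ones(n_cells, dtype=bool)
        for m in rule.anchors:
            anchor_ok &= positive[idx[m]]
        any_forbidden = np.zeros(n_cells, dtype=bool)
        for group in rule.forbidden:
            for m in group:
                any_forbidden |= positive[idx[m]]
        hits = anchor_ok & any_forbidden
        flagged |= hits
        for c in np.flatnonzero(hits):
            fired[c].append(rule.rule_id)
    return pd.DataFrame({
        "multiplet_flag": flagged,
        "rule_ids": [";".join(f) for f in fired],
    })


def annotate_cells(positive: np.ndarray, panel: list[str],
                   rules: MarkerRuleSet) -> pd.DataFrame:
    """Marker-precedence cell-type annotation.

    Precedence (first match wins): CD3+CD4 -> CD4_T, CD3+CD8 -> CD8_T,
    CD14 -> CD14_monocyte, CD19|CD20 -> B, CD56|CD16 -> NK, else
    unassigned. T cells are naive (CD45RA+ CD45RO-) or memory
    (CD45RO+ CD45RA-); cells positive for both get memory_state NA with a
    warning. ``activated`` is CD69 or CD25 positivity.
    """
    idx = {m: i for i, m in enumerate(panel)}
    n_cells = positive.shape[1]
    cell_type = np.full(n_cells, "unassigned", dtype=object)
    assigned = np.zeros(n_cells, dtype=bool)
    for step in rules.precedence:
        match = np.ones(n_cells, dtype=bool)
        for m in step.get("require_all", []):
            match &= positive[idx[m]]
        req_any = step.get("require_any", [])
        if req_any:
            any_hit = np.zeros(n_cells, dtype=bool)
            for m in req_any:
                any_hit |= positive[idx[m]]
            match &= any_hit
        match &= ~assigned
        cell_type[match] = step["cell_type"]
        assigned |= match

    is_t = np.isin(cell_type, ("CD4_T", "CD8_T"))
    ra = positive[idx[rules.naive_marker]]
    ro = positive[idx[rules.memory_marker]]
    memory_state = np.full(n_cells, "NA", dtype=object)
    memory_state[is_t & ra & ~ro] = "naive"
    memory_state[is_t & ro & ~ra] = "memory"
    n_both = int((is_t & ra & ro).sum())
    if n_both:
        log.warning("%d T cell(s) positive for both %s and %s; "
                    "memory_state set to NA", n_both, rules.naive_marker,
                    rules.memory_marker)

    activated = np.zeros(n_cells, dtype=bool)
    for m in rules.activation_markers:
        activated |= positive[idx[m]]
    return pd.DataFrame({
        "cell_type": cell_type,
        "memory_state": memory_state,
        "activated": activated,
    })


def annotate(adt: sp.spmatrix | np.ndarray, panel: list[str],
             barcodes: pd.Index, rules: MarkerRuleSet | None = None,
             seed: int = 0, clr_pseudocount: float = 1.0,
             threshold: float = 0.5) -> pd.DataFrame:
    """Full surface stage: CLR, positivity, multiplet rules, annotation."""
    if rules is None:
        rules = load_marker_rules()
    clr = clr_normalize(adt, pseudocount=clr_pseudocount)
    positive = call_positivity(clr, seed=seed, threshold=threshold)
    flags = apply_multiplet_rules(positive, panel, rules)
    ann = annotate_cells(positive, panel, rules)
    out = pd.concat([flags, ann], axis=1)
    out.insert(0, "barcode", pd.Index(barcodes))
    return out
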