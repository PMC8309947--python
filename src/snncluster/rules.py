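"""Spatiotemporal spike-event extraction and IF-THEN rule assembly.

A cluster's muPSP trace is thresholded into a binary event sequence (the
cluster "fires" wherever muPSP >= ell).  An action is an uninterrupted run of
window_L consecutive events, recorded at its starting time (baseline) and
tagged with a temporal order; the per-class rule conjoins the actions of all
clusters in baseline order:

    IF {CP4, ord1} AND {Fp2 F3, ord2} ... THEN Output = class

Actions whose baselines fall in the same length-window_L bin share one order
group.  Rules are explanatory artifacts; they are not used for classification.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EventSequence",
    "Action",
    "Rule",
    "extract_events",
    "default_event_threshold",
    "detect_actions",
    "assemble_rules",
    "render_rule",
    "parse_rule",
    "rule_to_json",
    "rule_from_json",
    "plot_event_raster",
]


@dataclass
class EventSequence:
    """Binary spike-event series of one cluster; c(t)=1 iff muPSP(t) >= ell."""

    cluster_id: int
    c: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=np.int8)
        if not np.isin(self.c, (0, 1)).all():
            raise ValueError("event series must be binary")


@dataclass
class Action:
    """A run of window_L consecutive events starting at ``baseline`` (1-based).

    ``baseline`` is None for actions recovered from rendered rule text, which
    carries only the (channels, ord) structure.
    """

    cluster_id: int
    baseline: int | None
    ord: int | None = None


@dataclass
class Rule:
    """IF A1 AND A2 AND ... AND An THEN Output = class."""

    class_output: int
    actions: list[Action] = field(default_factory=list)

    def __post_init__(self) -> None:
        ords = [a.ord for a in self.actions if a.ord is not None]
        if ords:
            uniq = sorted(set(ords))
            if uniq != list(range(1, len(uniq) + 1)):
                raise ValueError("ord values must form a contiguous 1..n sequence")


def default_event_threshold(mu_psp: np.ndarray) -> float:
    """Per-cluster spike-emitting threshold: mean + 1 SD of the muPSP trace."""
    mu_psp = np.asarray(mu_psp, dtype=float)
    return float(mu_psp.mean() + mu_psp.std())


def extract_events(mu_psp: np.ndarray, ell: float, cluster_id: int = 0) -> EventSequence:
    """Threshold a muPSP series into a binary event sequence (>= fires)."""
    mu_psp = np.asarray(mu_psp, dtype=float)
    if mu_psp.size == 0:
        raise ValueError("muPSP series must be nonempty")
    return EventSequence(cluster_id, (mu_psp >= ell).astype(np.int8), float(ell))


def detect_actions(
    events: EventSequence, window_L: int, inclusive_tail: bool = True
) -> list[Action]:
    """All-ones windows of length ``window_L`` as actions at their baselines.

    Baselines are 1-based; overlapping windows are each recorded.  By default
    every window up to baseline T - window_L + 1 is scanned; with
    ``inclusive_tail=False`` the scan stops at baseline T - window_L - 1 (the
    literal streaming loop bound, which can skip the trailing windows).
    Orders are not assigned here; see :func:`assemble_rules`.
    """
    T = len(events.c)
    if window_L < 1:
        raise ValueError("window_L must be >= 1")
    if window_L > T:
        raise ValueError("window_L must not exceed the series length")
    last = T - window_L + 1 if inclusive_tail else T - window_L - 1
    run = np.convolve(events.c, np.ones(window_L, dtype=int), mode="valid")
    return [
        Action(events.cluster_id, baseline)
        for baseline in range(1, last + 1)
        if run[baseline - 1] == window_L
    ]


def assemble_rules(
    actions: list[Action], class_output: int, group_div: int
) -> Rule:
    """Group actions into temporal order groups and assemble a class rule.

    Actions are sorted by baseline; baselines equal after integer division by
    ``group_div`` (normally the action window length) share one ord group, and
    ord values run 1..n in time order.  An empty action set yields the flagged
    degenerate rule "IF (no events) THEN Output = class".
    """
    if group_div < 1:
        raise ValueError("group_div must be >= 1")
    if not actions:
        warnings.warn(f"no actions for class {class_output}; degenerate rule emitted")
        return Rule(class_output, [])
    if any(a.baseline is None for a in actions):
        raise ValueError("actions must carry baselines to be assembled")
    ordered = sorted(actions, key=lambda a: (a.baseline, a.cluster_id))
    keys = sorted({a.baseline // group_div for a in ordered})
    key_to_ord = {k: i + 1 for i, k in enumerate(keys)}
    out = [
        Action(a.cluster_id, a.baseline, key_to_ord[a.baseline // group_div])
        for a in ordered
    ]
    return Rule(class_output, out)


def render_rule(rule: Rule, channel_names: list[str]) -> str:
    """Render a rule in the ``IF {ch, ord1} AND ... THEN Output = c`` syntax."""
    if not rule.actions:
        return f"IF (no events) THEN Output = {rule.class_output}"
    groups: dict[int, list[str]] = {}
    for a in rule.actions:
        names = groups.setdefault(a.ord, [])
        name = channel_names[a.cluster_id]
        if name not in names:
            names.append(name)
    clauses = [
        "{" + " ".join(groups[o]) + f", ord{o}" + "}" for o in sorted(groups)
    ]
    return "IF " + " AND ".join(clauses) + f" THEN Output = {rule.class_output}"


_CLAUSE_RE = re.compile(r"\{([^,{}]+),\s*ord(\d+)\}")
_OUTPUT_RE = re.compile(r"THEN Output\s*=\s*(\d+)")


def parse_rule(text: str, channel_names: list[str]) -> Rule:
    """Parse rendered rule text back into a :class:`Rule`.

    The text format carries no baselines, so the recovered actions have
    ``baseline=None``; the (channels, ord) grouping round-trips exactly.
    """
    m = _OUTPUT_RE.search(text)
    if m is None:
        raise ValueError("rule text has no THEN Output clause")
    class_output = int(m.group(1))
    if "(no events)" in text:
        return Rule(class_output, [])
    actions = []
    for clause in _CLAUSE_RE.finditer(text):
        names, order = clause.group(1).split(), int(clause.group(2))
        for name in names:
            actions.append(Action(channel_names.index(name), None, order))
    return Rule(class_output, actions)


def rule_to_json(rule: Rule) -> str:
    """Full-fidelity JSON export (cluster, baseline, ord per action)."""
    return json.dumps(
        {
            "class": rule.class_output,
            "actions": [
                {"cluster": a.cluster_id, "baseline": a.baseline, "ord": a.ord}
                for a in rule.actions
            ],
        }
    )


def rule_from_json(text: str) -> Rule:
    obj = json.loads(text)
    return Rule(
        obj["class"],
        [Action(a["cluster"], a["baseline"], a["ord"]) for a in obj["actions"]],
    )


def plot_event_raster(sequences: list[EventSequence], channel_names: list[str] | None = None, ax=None):
    """Raster of cluster spike events over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    for row, seq in enumerate(sequences):
        t = np.nonzero(seq.c)[0] + 1
        ax.vlines(t, row + 0.6, row + 1.4)
    labels = (
        [channel_names[s.cluster_id] for s in sequences]
        if channel_names is not None
        else [str(s.cluster_id) for s in sequences]
    )
    ax.set_yticks(np.arange(1, len(sequences) + 1), labels, fontsize=7)
    ax.set_xlabel("time point")
    return ax
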