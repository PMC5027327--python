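"""Map tree split attributes to brain lobes and compare subjects.

"Significant activity" in a lobe is operationalized as presence: a lobe is
present in a tree's report iff at least one of its electrodes appears as a
split attribute anywhere in the final tree — the inducer only spends a split
on an electrode whose values carry class information. Split depth is reported
for inspection but does not enter the presence decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

from .montage import LobeMap, _NAME_RE, default_lobe_map
from .tree import DecisionTreeModel, TreeNode


def parse_channel_name(name: str) -> tuple[str, str]:
    """Re-export of the 10-20 name parser (prefix, hemisphere)."""
    from .montage import parse_channel_name as _parse

    return _parse(name)


@dataclass(frozen=True)
class AttributionReport:
    """Which electrodes (and hence lobes) a tree's splits use."""

    electrodes_used: Mapping[str, int]
    electrode_min_depth: Mapping[str, int]
    lobes_present: frozenset[str]
    lobes_absent: frozenset[str]
    non_channel_attributes: frozenset[str]
    lobe_map: LobeMap

    def to_json(self) -> str:
        return json.dumps(
            {
                "electrodes_used": dict(self.electrodes_used),
                "electrode_min_depth": dict(self.electrode_min_depth),
                "lobes_present": sorted(self.lobes_present),
                "lobes_absent": sorted(self.lobes_absent),
                "non_channel_attributes": sorted(self.non_channel_attributes),
            },
            indent=2,
        )

    def format(self) -> str:
        lines = ["electrode splits:"]
        if not self.electrodes_used:
            lines.append("  (none)")
        for name, count in sorted(self.electrodes_used.items()):
            lobe = self.lobe_map.lobe_of(name)
            depth = self.electrode_min_depth[name]
            lines.append(f"  {name} ({lobe}): {count} node(s), min depth {depth}")
        lines.append(f"lobes present: {', '.join(sorted(self.lobes_present)) or '-'}")
        lines.append(f"lobes absent:  {', '.join(sorted(self.lobes_absent)) or '-'}")
        if self.non_channel_attributes:
            lines.append(
                "non-channel attributes: "
                + ", ".join(sorted(self.non_channel_attributes))
            )
        return "\n".join(lines)


def attribute_tree(
    model: DecisionTreeModel, lobe_map: LobeMap | None = None
) -> AttributionReport:
    """Count split-node usage per electrode and derive present/absent lobes.

    Attributes that look like 10-20 electrode names but are missing from the
    lobe map raise an error listing them; attributes that are not electrode
    names at all (e.g. ``Time``) are reported separately.
    """
    lobe_map = lobe_map or default_lobe_map()
    used: dict[str, int] = {}
    min_depth: dict[str, int] = {}
    non_channel: set[str] = set()
    missing: set[str] = set()

    def walk(node: TreeNode, depth: int) -> None:
        if node.is_leaf:
            return
        attr = node.split_attribute
        if attr in lobe_map:
            used[attr] = used.get(attr, 0) + 1
            min_depth[attr] = min(min_depth.get(attr, depth), depth)
        elif _NAME_RE.match(attr):
            missing.add(attr)
        else:
            non_channel.add(attr)
        walk(node.left, depth + 1)
        walk(node.right, depth + 1)

    walk(model.root, 0)
    if missing:
        raise ValueError(
            f"electrode(s) absent from the lobe map: {', '.join(sorted(missing))}"
        )
    present = frozenset(lobe_map.lobe_of(name) for name in used)
    return AttributionReport(
        electrodes_used=used,
        electrode_min_depth=min_depth,
        lobes_present=present,
        lobes_absent=lobe_map.lobes - present,
        non_channel_attributes=frozenset(non_channel),
        lobe_map=lobe_map,
    )


@dataclass(frozen=True)
class ComparisonSummary:
    """Lobe-presence differential between two attribution reports."""

    in_both: frozenset[str]
    only_in_a: frozenset[str]
    only_in_b: frozenset[str]

    def format(self, name_a: str = "A", name_b: str = "B") -> str:
        return "\n".join(
            [
                f"lobes in both:      {', '.join(sorted(self.in_both)) or '-'}",
                f"only in {name_a}:   {', '.join(sorted(self.only_in_a)) or '-'}",
                f"only in {name_b}:   {', '.join(sorted(self.only_in_b)) or '-'}",
            ]
        )


def compare_reports(
    a: AttributionReport, b: AttributionReport
) -> ComparisonSummary:
    """Lobes present in both reports, only in ``a``, and only in ``b``."""
    if dict(a.lobe_map.entries) != dict(b.lobe_map.entries):
        raise ValueError("reports were built over different lobe maps")
    return ComparisonSummary(
        in_both=a.lobes_present & b.lobes_present,
        only_in_a=a.lobes_present - b.lobes_present,
        only_in_b=b.lobes_present - a.lobes_present,
    )
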