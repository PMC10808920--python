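"""Machine-readable exports: area graphs, neuron-area graphs, summary tables.

Graphs carry structure and weights only; layout (e.g. force-directed
placement) is presentation and left to the consumer.  All exports are
deterministic given their inputs: nodes and edges are emitted in sorted
order and weights are written at full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_spikes import Session
from .motifs import COVERAGE_CATEGORIES, CoverageCategory, MotifRecord
from .stats import AreaPairStats, TestResult

_FORMATS = ("graphml", "dot", "tsv")


def _write_dot(G: nx.Graph, path: Path) -> None:
    directed = G.is_directed()
    kind = "digraph" if directed else "graph"
    arrow = "->" if directed else "--"
    lines = [f"{kind} G {{"]
    for node in sorted(G.nodes):
        attrs = G.nodes[node]
        extra = "".join(f' {k}="{v}"' for k, v in sorted(attrs.items()))
        lines.append(f'  "{node}" [{extra.strip()}];' if extra else f'  "{node}";')
    for u, v in sorted(G.edges):
        attrs = G.edges[u, v]
        extra = ", ".join(f'{k}="{v2}"' for k, v2 in sorted(attrs.items()))
        lines.append(f'  "{u}" {arrow} "{v}" [{extra}];' if extra else f'  "{u}" {arrow} "{v}";')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_graph(G: nx.Graph, fmt: str, path: str | Path) -> Path:
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "dot":
        _write_dot(G, path)
    elif fmt == "tsv":
        rows = [
            {"source": u, "target": v, **{k: w for k, w in sorted(G.edges[u, v].items())}}
            for u, v in sorted(G.edges)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}; choose from {_FORMATS}")
    return path


def build_area_graph(
    stats: Sequence[AreaPairStats],
    tests: Mapping[str, TestResult] | None = None,
    kind: str = "directional",
) -> nx.Graph:
    """Directed area graph (``kind="directional"``): focal -> partner edges
    weighted by the from-focal probability and partner -> focal edges by the
    to-focal probability.  Undirected variant (``kind="synchronous"``):
    weights are synchronous-pair probabilities.  Zero-probability edges are
    omitted.  ``tests`` (partner area -> direction TestResult) annotates the
    partner nodes with the asymmetry p-value."""
    if not stats:
        raise ValueError("no area-pair statistics")
    focal = stats[0].area_a
    G: nx.Graph = nx.DiGraph() if kind == "directional" else nx.Graph()
    G.add_node(focal, role="focal")
    for s in stats:
        if s.area_a != focal:
            raise ValueError("all stats must share the focal area")
        attrs = {"role": "partner"}
        if tests and s.area_b in tests and tests[s.area_b].tested:
            attrs["direction_p"] = tests[s.area_b].p_value
        G.add_node(s.area_b, **attrs)
        if kind == "directional":
            if s.p_from > 0:
                G.add_edge(focal, s.area_b, weight=s.p_from)
            if s.p_to > 0:
                G.add_edge(s.area_b, focal, weight=s.p_to)
        elif kind == "synchronous":
            if s.p_sync > 0:
                G.add_edge(focal, s.area_b, weight=s.p_sync)
        else:
            raise ValueError(f"unknown kind {kind!r}")
    return G


def export_area_graph(
    stats: Sequence[AreaPairStats],
    tests: Mapping[str, TestResult] | None,
    fmt: str,
    path: str | Path,
    kind: str = "directional",
) -> Path:
    """Write the area graph; GraphML round-trips weights exactly."""
    return _write_graph(build_area_graph(stats, tests, kind), fmt, path)


def build_neuron_graph(records: Sequence[MotifRecord], session: Session) -> nx.Graph:
    """Undirected bipartite-plus-internal graph of one session: focal units
    link to each other when they share an assembly, and to an external area
    node when at least one assembly involves that area."""
    focal = session.focal_area
    focal_units = [tr.unit_id for tr in session.trains if tr.area == focal]
    G = nx.Graph()
    for u in focal_units:
        G.add_node(u, kind="neuron")
    for area in session.areas:
        if area != focal:
            G.add_node(area, kind="area")
    for rec in records:
        a = rec.assembly
        in_focal = [u for u in a.unit_ids if u in focal_units]
        ext_areas = {ar for u, ar in zip(a.unit_ids, a.areas) if ar != focal}
        for i in range(len(in_focal)):
            for j in range(i + 1, len(in_focal)):
                G.add_edge(in_focal[i], in_focal[j])
            for area in ext_areas:
                G.add_edge(in_focal[i], area)
    return G


def export_neuron_graph(
    records: Sequence[MotifRecord], session: Session, fmt: str, path: str | Path
) -> Path:
    return _write_graph(build_neuron_graph(records, session), fmt, path)


def _percent(counts: Mapping[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: 100.0 * v / total for k, v in counts.items()}


def delay_histogram(records: Sequence[MotifRecord]) -> pd.DataFrame:
    """Signed delays (ms) of external pairs per partner area.

    Positive = from-focal (focal unit leads), negative = to-focal, zero =
    synchronous; delay magnitude is ``lag * bin_size``.
    """
    rows = []
    for rec in records:
        if rec.klass not in ("pair_synchronous", "pair_from_focal", "pair_to_focal"):
            continue
        a = rec.assembly
        delay_ms = a.lags_bins[1] * a.bin_size * 1000.0
        if rec.klass == "pair_to_focal":
            delay_ms = -delay_ms
        rows.append({"partner_area": rec.partner_area, "delay_ms": delay_ms})
    df = pd.DataFrame(rows, columns=["partner_area", "delay_ms"])
    if df.empty:
        return df.assign(count=pd.Series(dtype=int))
    out = (
        df.groupby(["partner_area", "delay_ms"]).size().rename("count").reset_index()
    )
    return out.sort_values(["partner_area", "delay_ms"]).reset_index(drop=True)


def summary_tables(
    records: Sequence[MotifRecord],
    stats: Sequence[AreaPairStats],
    coverages: Sequence[CoverageCategory],
) -> dict:
    """Bundle of summary tables: area rankings by pair and loop probability,
    the directional vs synchronous split for internal and external pairs
    (percentages summing to 100 within each group), coverage-category
    percentages, and the signed delay histogram."""
    from .stats import rank_areas

    ext = [r for r in records if r.klass in ("pair_synchronous", "pair_from_focal", "pair_to_focal")]
    internal = [r for r in records if r.klass == "pair_internal_focal"]
    split = {}
    for name, group in (("external", ext), ("internal", internal)):
        counts = {
            "directional": sum(1 for r in group if not r.synchronous),
            "synchronous": sum(1 for r in group if r.synchronous),
        }
        split[name] = {"counts": counts, "percent": _percent(counts)}

    cov_counts = {c: 0 for c in COVERAGE_CATEGORIES}
    for c in coverages:
        cov_counts[c.category] += 1

    return {
        "ranking_pairs": rank_areas(stats, "pairs") if stats else pd.DataFrame(),
        "ranking_loops": rank_areas(stats, "loops") if stats else pd.DataFrame(),
        "directional_split": split,
        "coverage": {"counts": cov_counts, "percent": _percent(cov_counts)},
        "delay_histogram": delay_histogram(records),
    }


def write_report(tables: dict, outdir: str | Path) -> Path:
    """Write the summary bundle: TSV per table, JSON for the dict parts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("ranking_pairs", "ranking_loops", "delay_histogram"):
        df = tables[name]
        if isinstance(df, pd.DataFrame):
            df.to_csv(outdir / f"{name}.tsv", sep="\t")
    payload = {
        "directional_split": tables["directional_split"],
        "coverage": tables["coverage"],
    }
    (outdir / "summary.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8"
    )
    return outdir
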