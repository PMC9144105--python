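"""End-to-end analysis: network -> metrics -> cohort -> comparison.

`analyze_network` runs validation, branch ordering, segment metrics,
bifurcation measurement, ring-unit decomposition and anomaly
detection on one network. `analyze_cohort` pools a group of networks
(one animal each); `compare_cohorts` assembles the two-group report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import anomalies as anom
from . import branching, rings, segments, stats
from .config import AnalysisConfig
from .model import VascularNetwork, validate_network

__all__ = ["NetworkAnalysis", "CohortResult", "analyze_network", "analyze_cohort", "compare_cohorts"]


@dataclass
class NetworkAnalysis:
    network: VascularNetwork
    segment_metrics: pd.DataFrame
    bifurcations: list[branching.Bifurcation]
    ring_units: pd.DataFrame
    anomaly_instances: list[anom.AnomalyInstance]


def analyze_network(network: VascularNetwork, config: AnalysisConfig | None = None) -> NetworkAnalysis:
    """Run the full single-network pipeline."""
    cfg = config or AnalysisConfig()
    report = validate_network(network, cfg.coincidence_tol)
    if report.errors:
        first = report.errors[0]
        raise ValueError(
            f"validation failed ({first.code} on entity {first.entity}): {first.message}"
        )
    metrics = segments.compute_segment_metrics(
        network, cfg.order_scheme, cfg.diam_agg, cfg.direct_anchor
    )
    bifs = branching.extract_bifurcations(
        network,
        cfg.angle_chord,
        cfg.lateral_angle_threshold,
        cfg.lateral_asymmetry_threshold,
        cfg.murray_exponent,
    )
    units = rings.decompose_network(network, cfg.unit_length, cfg.remainder_policy)
    instances = anom.detect_all(
        network,
        tortuosity_threshold=cfg.tortuosity_threshold,
        parallel_max_gap=cfg.parallel_max_gap,
        parallel_max_angle=cfg.parallel_max_angle,
        parallel_min_overlap=cfg.parallel_min_overlap,
        broken_angle_threshold=cfg.broken_angle_threshold,
        units=units,
    )
    return NetworkAnalysis(network, metrics, bifs, units, instances)


@dataclass
class CohortResult:
    """Pooled results for one group of networks."""

    name: str
    analyses: list[NetworkAnalysis]
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    @property
    def n_networks(self) -> int:
        return len(self.analyses)

    def _norm(self) -> float:
        return self.config.normalize_to_n / self.n_networks

    def segment_total(self) -> float:
        """Pooled segment count, normalized to the reference cohort size."""
        return sum(len(a.segment_metrics) for a in self.analyses) * self._norm()

    def ring_total(self) -> float:
        """Pooled 50 um ring-unit count, normalized."""
        return sum(len(a.ring_units) for a in self.analyses) * self._norm()

    def pooled_units(self) -> pd.DataFrame:
        return pd.concat([a.ring_units for a in self.analyses], ignore_index=True)

    def pooled_bifurcations(self) -> list[branching.Bifurcation]:
        return [b for a in self.analyses for b in a.bifurcations]

    def diameter_histogram(self, which: str = "outer") -> rings.DiameterHistogram:
        return rings.diameter_histogram(
            self.pooled_units(),
            self.config.diam_bin_pitch,
            self.config.normalize_to_n,
            self.n_networks,
            which,
        )

    def distance_diameter_histogram(self) -> rings.DistanceDiameterHistogram:
        return rings.distance_diameter_histogram(
            self.pooled_units(), self.config.diam_bin_pitch, self.config.dist_bin_pitch
        )

    def per_network_mean(self, column: str, selector=None) -> np.ndarray:
        """Mean of a segment-metric column per network (optionally on a
        row subset, e.g. first-order segments only)."""
        vals = []
        for a in self.analyses:
            df = a.segment_metrics
            if selector is not None:
                df = df[selector(df)]
            vals.append(float(df[column].mean()) if len(df) else np.nan)
        return np.asarray(vals)

    def anomalies(self) -> anom.AnomalyReport:
        raw = dict.fromkeys(anom.ANOMALY_CLASSES, 0.0)
        evidence = []
        for a in self.analyses:
            for inst in a.anomaly_instances:
                raw[inst.anomaly_class] += 1.0
                evidence.append(inst)
        counts = {k: v * self._norm() for k, v in raw.items()}
        return anom.AnomalyReport(counts, self.n_networks, self.config.normalize_to_n, evidence)

    def asymmetry_angle(self):
        """(Pearson r, p, slope) of branch angle on A_i, bifurcations
        pooled across the cohort's networks."""
        return branching.asymmetry_angle_relation(self.pooled_bifurcations())

    def murray_fit(self, bootstrap: int = 0, seed: int | None = None):
        return branching.fit_murray_exponent(self.pooled_bifurcations(), bootstrap, seed)


def analyze_cohort(
    networks: list[VascularNetwork],
    name: str = "cohort",
    config: AnalysisConfig | None = None,
) -> CohortResult:
    cfg = config or AnalysisConfig()
    if not networks:
        raise ValueError("empty cohort")
    return CohortResult(name, [analyze_network(n, cfg) for n in networks], cfg)


def compare_cohorts(cohort_a: CohortResult, cohort_b: CohortResult) -> stats.GroupComparisonReport:
    if cohort_a.config != cohort_b.config:
        raise ValueError("cohorts were analyzed with different configurations")
    return stats.build_group_report(cohort_a, cohort_b, cohort_a.config.min_expected)
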