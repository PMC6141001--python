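"""End-to-end composition of the imaging pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import DomainAnnotation, annotate_cohort
from .io import AnalysisConfig, FiberSection
from .overlap import OverlapCohortResult, overlap_record, overlap_test, cohort_fractions
from .profiling import PerimeterProfile, profile_cohort

__all__ = ["OverlapPipelineOutput", "analyze_sections"]


@dataclass
class OverlapPipelineOutput:
    profiles: list[PerimeterProfile]
    annotations: list[DomainAnnotation]
    result: OverlapCohortResult
    aggregates: dict


def analyze_sections(
    sections: list[FiberSection],
    config: AnalysisConfig | None = None,
    manual: dict | None = None,
) -> OverlapPipelineOutput:
    """Profile a cohort of fiber sections, annotate perinuclear and focal
    domains, and run the overlap significance test."""
    config = config or AnalysisConfig()
    profiles = profile_cohort(sections, config)
    annotations = annotate_cohort(profiles, config, manual=manual)
    records = [overlap_record(a) for a in annotations]
    result = overlap_test(records)
    return OverlapPipelineOutput(
        profiles=profiles,
        annotations=annotations,
        result=result,
        aggregates=cohort_fractions(records),
    )
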