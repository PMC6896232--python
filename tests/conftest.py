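"""Shared fixtures: a simulated three-lineage study and the documented
five-edge regulatory scenario, both session-scoped (they are deterministic
and moderately expensive to generate)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from germnet import activity, counts, grn, synth


@pytest.fixture(scope="session")
def study() -> synth.SimulatedStudy:
    """Default three-condition differentiation study (seed 5)."""
    return synth.simulate_study(synth.GeneratorConfig(seed=5))


@pytest.fixture(scope="session")
def study_expr(study) -> counts.ExpressionMatrix:
    return counts.normalize(study.counts)


@pytest.fixture(scope="session")
def scenario() -> synth.RegulatoryScenario:
    return synth.regulatory_scenario()


@pytest.fixture(scope="session")
def scenario_network(scenario):
    """Fitted activities and inferred network for the five-edge scenario."""
    expr = counts.normalize(scenario.counts)
    model = activity.motif_significance(expr.log2_expr, scenario.sites,
                                        alpha=0.01)
    net = grn.infer_edges(model, expr, scenario.sites, scenario.tf_gene_map,
                          threshold=0.8)
    return expr, model, net


def make_expression(rpm: pd.DataFrame,
                    pseudocount: float = 1.0) -> counts.ExpressionMatrix:
    """ExpressionMatrix from a plain rpm frame (metadata parsed from names)."""
    meta = pd.DataFrame([counts.parse_sample_name(s) for s in rpm.columns],
                        index=rpm.columns,
                        columns=["condition", "day", "replicate"])
    return counts.ExpressionMatrix(rpm, meta,
                                   pd.Series(1.0, index=rpm.columns),
                                   pseudocount=pseudocount)
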