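"""Shared fixtures: hand-built report sets and a small synthetic database."""

from __future__ import annotations

import pytest

import pvsignal as pv


@pytest.fixture(scope="session")
def small_config() -> pv.GeneratorConfig:
    """Default pediatric generator scaled down for fast unit tests."""
    cfg = pv.default_pediatric_config(scale=1, seed=20230612)
    return cfg.model_copy(update={"n_reports": 6000})


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One generated (ReportSet, GroundTruth) pair reused across tests."""
    return pv.generate_report_set(small_config)


@pytest.fixture()
def catatonia_query() -> pv.PtQuery:
    return pv.PtQuery(name="catatonia", pts=frozenset({"catatonia"}))


@pytest.fixture()
def hand_reports() -> pv.ReportSet:
    """Six hand-written pediatric reports: 2 drug+reaction, 1 drug-only,
    1 reaction-only, 2 neither (for contingency hand counts)."""
    mk = pv.make_report
    reports = [
        mk("r1", 15, "years", ["olanzapine"], ["catatonia", "pyrexia"]),
        mk("r2", 14, "years", ["olanzapine", "lorazepam"], ["catatonia"]),
        mk("r3", 16, "years", ["olanzapine"], ["rash"]),
        mk("r4", 13, "years", ["ibuprofen"], ["catatonia", "seizure"]),
        mk("r5", 15, "years", ["paracetamol"], ["headache"]),
        mk("r6", 17, "years", ["sertraline"], ["nausea"]),
    ]
    return pv.ReportSet(reports=reports, provenance="hand")
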