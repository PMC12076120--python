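import numpy as np
import pandas as pd
import pytest

from vigimr.simulate import InjectedSignal, ReportSimConfig, simulate_reports


def make_report_frame(rows):
    """Build a minimal report frame from (report_id, case_id, version, drug,
    role, pt, sex, age, event, start) tuples; trailing fields may be omitted."""
    defaults = ("F", 40.0, "2020-01-10", "2020-01-01")
    full = [tuple(r) + defaults[len(r) - 6 :] for r in rows]
    df = pd.DataFrame(
        full,
        columns=[
            "report_id",
            "case_id",
            "version",
            "drug_name",
            "role_code",
            "pt_name",
            "sex",
            "age_years",
            "event_date",
            "start_date",
        ],
    )
    df["event_date"] = pd.to_datetime(df["event_date"])
    df["start_date"] = pd.to_datetime(df["start_date"])
    return df


@pytest.fixture
def tiny_reports():
    return make_report_frame(
        [
            ("R1", "C1", 0, "DrugA", "PS", "Depression"),
            ("R2", "C2", 0, "DrugA", "PS", "Nausea"),
            ("R3", "C3", 0, "DrugB", "PS", "Depression"),
            ("R4", "C4", 0, "DrugB", "PS", "Nausea"),
        ]
    )


def sim_config(**overrides) -> ReportSimConfig:
    base = dict(
        n_reports=5000,
        drugs={"DrugA": 0.15, "DrugB": 0.15},
        psychiatric_pts=[f"Psy{i}" for i in range(5)],
        other_pts=[f"Oth{i}" for i in range(15)],
        injected_signals=[],
        seed=0,
    )
    base.update(overrides)
    signals = base.pop("injected_signals")
    return ReportSimConfig(
        injected_signals=[
            s if isinstance(s, InjectedSignal) else InjectedSignal(*s) for s in signals
        ],
        **base,
    )


@pytest.fixture
def null_simulated():
    """A moderate null simulation shared by several tests."""
    return simulate_reports(sim_config(n_reports=10_000, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
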