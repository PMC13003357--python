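import numpy as np
import pytest

from ahrqsar.curation import DoseResponseRecord


def twelve_record_fixture() -> list[DoseResponseRecord]:
    """Twelve records, eight of which each trip exactly one exclusion rule
    (in the fixed rule order) and four of which survive curation."""
    return [
        # --- one record per exclusion reason ---
        DoseResponseRecord("X_purity", purity_pct=85.0, ec25_ahr_uM=5.0),
        DoseResponseRecord(
            "X_mixture", purity_pct=99.0, ec25_ahr_uM=5.0, is_mixture_or_inorganic=True
        ),
        DoseResponseRecord("X_band", purity_pct=99.0, ec25_ahr_uM=500.0),
        DoseResponseRecord(
            "X_cyto3", purity_pct=99.0, ec25_ahr_uM=10.0, ec20_cyto_uM=25.0
        ),
        DoseResponseRecord("X_icyto", purity_pct=99.0, ec20_cyto_uM=50.0),
        DoseResponseRecord("X_cas", purity_pct=99.0, has_defined_cas=False),
        DoseResponseRecord(
            "X_rep", purity_pct=99.0, ec25_ahr_uM=0.5, replicate_ec25_uM=[0.5, 50.0]
        ),
        DoseResponseRecord(
            "X_curve", purity_pct=99.0, ec25_ahr_uM=5.0, atypical_curve=True
        ),
        # --- four clean survivors, one per activity band ---
        DoseResponseRecord("K_high", purity_pct=99.0, ec25_ahr_uM=0.5),
        DoseResponseRecord("K_medium", purity_pct=95.0, ec25_ahr_uM=5.0),
        DoseResponseRecord("K_low", purity_pct=99.0, ec25_ahr_uM=50.0, ec20_cyto_uM=200.0),
        DoseResponseRecord("K_inactive", purity_pct=99.0),
    ]


@pytest.fixture
def rule_fixture():
    return twelve_record_fixture()


def random_records(rng: np.random.Generator, n: int) -> list[DoseResponseRecord]:
    """Records spanning all rule-relevant regimes, for property tests."""
    records = []
    for i in range(n):
        purity = None if rng.random() < 0.1 else float(rng.uniform(80, 100))
        regime = rng.random()
        if regime < 0.45:
            ec25 = None
        elif regime < 0.85:
            ec25 = float(np.exp(rng.uniform(np.log(1e-3), np.log(100))))
        elif regime < 0.95:
            ec25 = float(np.exp(rng.uniform(np.log(100.5), np.log(1000))))
        else:
            ec25 = float(rng.uniform(1001, 5000))
        ec20 = (
            None
            if rng.random() < 0.6
            else float(np.exp(rng.uniform(np.log(0.1), np.log(500))))
        )
        reps = []
        if ec25 is not None and rng.random() < 0.3:
            reps = [
                float(np.exp(rng.uniform(np.log(1e-3), np.log(200))))
                for _ in range(int(rng.integers(2, 4)))
            ]
        records.append(
            DoseResponseRecord(
                compound_id=f"R{i:05d}",
                purity_pct=purity,
                ec25_ahr_uM=ec25,
                ec20_cyto_uM=ec20,
                is_mixture_or_inorganic=bool(rng.random() < 0.05),
                replicate_ec25_uM=reps,
                has_defined_cas=bool(rng.random() > 0.05),
                atypical_curve=bool(rng.random() < 0.05),
            )
        )
    return records
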