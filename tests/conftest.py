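import pandas as pd
import pytest
from hypothesis import settings

from masplan.markers import GenotypePanel

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def build_panel(rows: dict[str, tuple[str, str, dict[str, str | None]]]) -> GenotypePanel:
    """Panel from {line_id: (role, status, {marker: call-or-None})}."""
    lines = pd.DataFrame(
        {lid: {"role": role, "qtl_status": status}
         for lid, (role, status, _) in rows.items()}
    ).T.rename_axis("line_id")
    markers: list[str] = []
    for _, _, calls in rows.values():
        for m in calls:
            if m not in markers:
                markers.append(m)
    calls = pd.DataFrame(
        [[rows[lid][2].get(m) for m in markers] for lid in rows],
        index=lines.index,
        columns=markers,
        dtype="string",
    )
    return GenotypePanel(lines, calls)


@pytest.fixture
def validation_panel() -> GenotypePanel:
    """Two donors (QTL-positive) and five recipients (QTL-negative)
    graded with three candidate markers: one with a false negative on
    the second donor (FNR 1/2), one calling three recipients positive
    (false positives), and one fully concordant."""
    def calls(m1, m2, m3):
        return {"m1": m1, "m2": m2, "m3": m3}

    return build_panel({
        "donor_1": ("donor", "positive", calls("A", "A", "A")),
        "donor_2": ("donor", "positive", calls("B", "A", "A")),
        "recipient_1": ("recipient", "negative", calls("B", "B", "B")),
        "recipient_2": ("recipient", "negative", calls("B", "A", "B")),
        "recipient_3": ("recipient", "negative", calls("B", "B", "B")),
        "recipient_4": ("recipient", "negative", calls("B", "A", "B")),
        "recipient_5": ("recipient", "negative", calls("B", "A", "B")),
    })
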