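"""Validate a MIAPPE workbook and see how defects are reported.

Generates a small synthetic deposit, validates it (clean), then injects a
date-less event — the classic under-documented management action — and
validates again.  The report lists machine-readable error codes, so a
curator can fix a legacy deposit one code at a time.
"""

import tempfile
from pathlib import Path

from phenofair.model import validate_investigation
from phenofair.synth import FixtureSpec, generate_fixture, perturb_fixture
from phenofair.tabular import read_miappe_workbook, read_observation_table

with tempfile.TemporaryDirectory() as tmp:
    fx = generate_fixture(FixtureSpec.small(seed=1), Path(tmp) / "deposit")

    inv, report = read_miappe_workbook(fx.paths["workbook"])
    records = []
    for sid, path in sorted(fx.paths["observations"].items()):
        records.extend(read_observation_table(path, inv))
    print("clean deposit:", validate_investigation(inv, records))

    info = perturb_fixture(fx, "dateless_event", Path(tmp) / "broken")
    inv2, _ = read_miappe_workbook(info["dir"] / "workbook")
    print("\nafter injecting an un-dated management event:")
    print(validate_investigation(inv2))

# The second report shows EVT_DATE_MISSING: an event without a date cannot
# be represented in MIAPPE and must move to the experimental factors.
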