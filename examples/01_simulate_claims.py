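"""Generate a synthetic linked mother-infant claims bundle.

Draws 500 mothers with realistic gestation lengths, antenatal visit
schedules, delivery-entry coverage, and Kampo dispensing records; then
applies the date-missingness layer and writes the five CSV tables plus the
generator's ground truth.
"""
from pathlib import Path

from kampo_claims import SimParams, degrade_dates, simulate_bundle, write_claims_bundle

params = SimParams(n_mothers=500, seed=7)
bundle, truth = simulate_bundle(params)
bundle = degrade_dates(bundle, params)

out = Path("scratch/example_bundle")
write_claims_bundle(bundle, out)
truth.write_csv(out / "ground_truth.csv")

n_kampo = sum(d.atc_code.startswith("V03AX") for d in bundle.drugs)
n_eligible = sum(ep.eligible for ep in truth.episodes.values())
print(f"mothers simulated:      {params.n_mothers}")
print(f"persons (with infants): {len(bundle.persons)}")
print(f"diagnosis records:      {len(bundle.diagnoses)}")
print(f"delivery entries:       {len(bundle.delivery_entries)}")
print(f"drug records:           {len(bundle.drugs)} ({n_kampo} Kampo, ATC V03AX)")
print(f"truly eligible mothers: {n_eligible}")
print(f"tables written to {out}/")
# Each mother's true onset/delivery dates and true per-window prescriptions
# are in ground_truth.csv, so downstream estimates can be scored exactly.
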