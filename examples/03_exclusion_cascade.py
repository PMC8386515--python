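"""Apply the preregistered exclusion cascade to a simulated cohort.

Each excluded participant is attributed exactly one reason — the first
criterion failed, in preregistered order — so the per-reason counts plus
the included count always reconcile with the cohort size.
"""

from antlook import (
    SimulationParams,
    apply_exclusions,
    build_record,
    load_aois,
    load_paradigm_config,
    simulate_cohort,
)

params = SimulationParams(seed=42, n_per_condition_per_site=20)  # 80 infants
aois, cfg = load_aois(), load_paradigm_config()
records = [build_record(raw, aois, cfg) for raw in simulate_cohort(params)]

main, fam2_incorrect, ledger = apply_exclusions(records)
summary = ledger.summary()

print(f"{summary['total']} tested, {summary['included']} in the main sample")
for reason, count in summary["by_reason"].items():
    print(f"  excluded, {reason:<24s} {count}")
print(f"fam2-incorrect follow-up sample: {len(fam2_incorrect)}")
check = summary["included"] + sum(summary["by_reason"].values())
print(f"conservation: {summary['included']} + excluded = {check} = total")
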