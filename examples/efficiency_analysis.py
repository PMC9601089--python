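"""Quantify the annotation-time savings of auto-partitioned sprints.

Simulates a four-person team annotating a control sprint (unfiltered
view mix) and an auto-partitioned sprint (mostly relevant parenchymal
clips), computes per-annotator throughput, runs one-sided paired
t-tests, and extrapolates the per-clip skip cost to a 100,000-clip
database.
"""

from lusview import (
    EventGenConfig,
    ExtrapolationSpec,
    SprintKind,
    extrapolate_savings,
    generate_event_log,
    make_sprint_mix,
    sprint_metrics,
    sprint_time_saved,
)

control = generate_event_log(
    make_sprint_mix(351, 383, 46, prefix="ctl"), EventGenConfig(seed=1), SprintKind.CONTROL
)
auto = generate_event_log(
    make_sprint_mix(701, 35, 44, prefix="auto"), EventGenConfig(seed=2), SprintKind.AUTO_PARTITIONED
)
report = sprint_metrics(control + auto)

print(report.per_annotator.round(2).to_string(index=False))
for metric, (t, p, direction) in report.paired_tests.items():
    print(f"{metric}: t = {t:+.2f}, one-sided p = {p:.4f} (auto {direction} than control)")

wide = report.per_annotator.pivot(index="annotator_id", columns="sprint_kind",
                                  values="skip_time_min")
saved = sprint_time_saved(wide["control"].to_numpy(), wide["auto_partitioned"].to_numpy())
print(f"\nskip time saved across the team this sprint: {saved:.1f} min")

seconds, days = extrapolate_savings(ExtrapolationSpec(
    mean_skip_s=8.5, frac_irrelevant_control=0.49, frac_irrelevant_auto=0.04,
    n_clips=100_000,
))
print(f"extrapolated to a 100,000-clip database: {seconds:,.0f} s ~ {days:.2f} days")
print("Labels/hour rise and skip time collapses in the auto-partitioned sprint")
print("because annotators rarely touch irrelevant pleural clips at all.")
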