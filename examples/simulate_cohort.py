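"""Trace one incident cohort through the tunnel state space.

Loads the packaged male transition table, starts a unit cohort of newly
diagnosed 55-59-year-old diabetics, and prints where the cohort mass sits
after 1, 5, 10 and 25 one-year cycles.
"""

from dmburden import RunConfig, load_fixture_tables, simulate_cohort

table, _ = load_fixture_tables()
config = RunConfig()
trace = simulate_cohort("male", "55-59", table, config)

print("cycle  age  uncomplicated  complicated  dead(dm)  dead(other)")
for cycle in (0, 1, 5, 10, 25):
    occ = trace.occupancy[cycle]
    print(
        f"{cycle:5d}  {trace.ages[cycle]:3d}"
        f"  {trace.uncomplicated_mass[cycle]:13.4f}"
        f"  {trace.complicated_mass[cycle]:11.4f}"
        f"  {occ[-2]:8.4f}  {occ[-1]:11.4f}"
    )

# The uncomplicated column is the mass still in the diabetes-only states
# (incident tunnel + prevalent); complication onset drains it into the
# complication states, and the two absorbing death columns only ever grow.
print(f"\nmass check (should be 1): {trace.occupancy[25].sum():.12f}")
print(f"ever complicated by cycle 25: {trace.new_ci[:26].sum():.4f}")
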