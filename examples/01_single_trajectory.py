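"""Fold one RNA molecule from the open chain to its MFE structure.

Runs a single stochastic trajectory of the bundled 29-nt example under
Turner-rules energies and prints a handful of stages along the path.
"""

import ssafold as sf

seq = sf.EXAMPLE_SMOOTH
energy = sf.TurnerEnergyModel()          # ViennaRNA-backed
config = sf.SimulationConfig(energy=energy,
                             rates=sf.RateModel("metropolis", energy.RT))
target, mfe = energy.mfe(seq)

traj = sf.simulate_fold(seq, sf.open_chain(len(seq)), target, config,
                        seed=7)

print(f"sequence  {seq}")
print(f"target    {target}  ({mfe:.2f} kcal/mol)")
print(f"reached the target after {traj.n_steps} elementary moves, "
      f"first-passage time {traj.first_passage_time:.1f} (arbitrary units)")
print("\nsix stages along the trajectory (time, structure, kcal/mol):")
step = max(1, len(traj.records) // 5)
for t, s, e in traj.records[::step][:5] + [traj.records[-1]]:
    print(f"  t={t:10.2f}  {s}  {e:7.2f}")
# Each line is one visited secondary structure; the energy drifts downhill
# on average but individual moves can go uphill (Metropolis rule).
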