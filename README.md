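# neuroforward

Forward modeling of the electric and magnetic signatures of neural activity.
Given a passive multicompartment neuron model (or a population of them),
`neuroforward` computes the transmembrane and intracellular axial currents
and maps them onto every standard measurement modality:

- **LFP / MUA** — extracellular potentials inside tissue, via point-source,
  line-source and soma-as-point kernels in homogeneous, anisotropic and
  layered (method-of-images) volume conductors, with disc-electrode surface
  averaging;
- **MEA / ECoG** — slice-on-chip three-layer and cortical-surface two-layer
  image models, plus a one-sphere conductor for monopole sources;
- **EEG** — current-dipole forward solutions for the infinite homogeneous
  medium and the corrected four-concentric-sphere head model
  (brain / CSF / skull / scalp);
- **MEG** — the magnetostatic dipole field **B** = μ₀/4π · **p**×**R**/R³ and
  the near-field Biot–Savart sum over axial current elements;
- **networks** — stochastic wiring of recurrently connected multicompartment
  populations (Bernoulli connectivity without autapses, multapse counts,
  capped-normal delays and conductances, layer-specific synapse placement,
  Poisson drive) with extracellular potentials and dipole moments
  accumulated during the simulation.

It is aimed at computational neuroscientists who want to relate mechanistic
single-cell and microcircuit models to the signals experimentalists record,
without an external simulator: an internal Crank–Nicolson solver integrates
the passive cable equations on branched morphologies.

## The physics in one paragraph

Under the quasistatic approximation, an ohmic extracellular medium maps each
transmembrane current `I_n(t)` at position `r_n` linearly onto the potential
at an electrode, `φ(r, t) = Σ_n M(r, r_n) I_n(t)`, with the kernel `M` set
by the volume conductor (e.g. `1/(4πσ_e|r − r_n|)` for a point source in a
homogeneous medium). Because current monopoles vanish by charge
conservation, the far field is governed by the current dipole moment
`p(t) = Σ_n r_n I_n(t)`, which can equivalently be assembled from axial
currents as `Σ_m I_m(t) d_m` — including *virtual* current elements where a
branch attaches mid-section, an identity the library maintains to machine
precision. `p` feeds the EEG head models (`φ_p = p·R/4πσR³` and the
four-sphere Legendre series) and the MEG field, while near the cell the
magnetic field follows from the axial currents directly.

## Worked example

A stylized passive pyramidal cell (soma at the origin, 1 mm apical trunk
with tuft, oblique and basal dendrites, all in the xz-plane) receives one
excitatory synapse at the top of its trunk; we predict every modality from
the same simulation:

```python
import numpy as np
from neuroforward import (make_stylized_pyramidal, PassiveParams, SynapseSpec,
                          simulate, axial_currents, center_of_areas,
                          dipole_from_transmembrane, dipoles_from_axial,
                          ProbeSpec, Homogeneous, kernel_matrix,
                          FourSphereModel, SurfaceGrid, four_sphere_potential,
                          DipoleMoment, surface_field_components)

cell = make_stylized_pyramidal(seed=1)
trunk_top = int(np.flatnonzero(cell.section_id == 1)[-1])
syn = SynapseSpec(segment=trunk_top, onsets=(2.0,), tau_r=0.2, tau_d=1.7,
                  g_max=2.0, e_syn=0.0)                      # AMPA-like, nS
sim = simulate(cell, PassiveParams(), synapses=[syn], T=30.0)
print(f"somatic EPSP peak: {sim.v_m[0].max():.2f} mV (rest {sim.v_m[0,0]:.0f} mV)")

depths = -np.arange(0.0, 1501.0, 300.0)
probe = ProbeSpec(np.column_stack([np.full_like(depths, 50.0),
                                   np.zeros_like(depths), depths]),
                  medium=Homogeneous(0.3), source_model="soma_as_point")
lfp = kernel_matrix(cell, probe) @ sim.i_m
print(f"peak |LFP| at 50 um lateral: {1e3 * np.abs(lfp).max():.2f} uV")

p = dipole_from_transmembrane(sim.i_m, cell.mid, location=center_of_areas(cell))
_per, p_ax = dipoles_from_axial(axial_currents(cell, sim.v_m))
print(f"peak |p_z|: {np.abs(p.p[2]).max() * 1e3:.3f} pAm;  "
      f"transmembrane vs axial route max difference: "
      f"{np.abs(p.p - p_ax.p).max():.2e} nAm")

head = FourSphereModel()           # radii 79/80/85/90 mm, sigma 0.3/1.5/0.015/0.3
p_head = DipoleMoment(p.p, location=np.array([0.0, 0.0, 78.0]))
arc = SurfaceGrid.arc_xz(head.radii[3])        # 9 scalp sites, ~18 mm apart
eeg = four_sphere_potential(head, p_head, arc.points)
k = int(np.argmax(np.abs(p.p[2])))
print(f"EEG at the apex site: {eeg[4, k] * 1e3:.3f} nV at peak dipole")
_br, _bt, bphi = surface_field_components(p_head, arc)
print(f"MEG |B_phi| at site 4: {np.abs(bphi[3]).max() * 1e15:.3f} fT")
```

Output:

```
somatic EPSP peak: -76.48 mV (rest -77 mV)
peak |LFP| at 50 um lateral: 0.03 uV
peak |p_z|: 0.019 pAm;  transmembrane vs axial route max difference: 8.84e-18 nAm
EEG at the apex site: -0.021 nV at peak dipole
MEG |B_phi| at site 4: 0.004 fT
```

Reading the numbers: a single 2 nS synapse depolarizes the soma by half a
millivolt and produces tens of nanovolts of LFP close to the cell; its
dipole moment (~0.02 pAm, dominated by the vertical component because the
cell is vertical) yields sub-nanovolt scalp EEG and attotesla-scale MEG — the reason measurable EEG/MEG requires thousands of synchronously
activated cells. The dipole computed from transmembrane currents and from
axial currents (with virtual elements at the mid-trunk attachment) agree to
1e-17 nAm.

There is also a thin CLI (`nf morph`, `nf simulate`, `nf lfp`, `nf dipole`,
`nf eeg`, `nf meg`, `nf network`) for file-based pipelines; run
`nf --help`.

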