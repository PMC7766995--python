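# dendromd

Trajectory analysis of charged peptide dendrimers: structure,
electrostatic double layer, hydrogen bonds, and NMR spin-lattice
relaxation from orientational autocorrelation functions.

Cationic lysine-based dendrimers with dipeptide spacers (Lys-2Arg,
Lys-2Lys) are gene-delivery vehicles whose NMR fingerprints differ even
though their structures are nearly identical: the spin-lattice relaxation
of the side CH2-N groups in 2Arg spacers is much slower than in 2Lys
spacers.  The analyses in this package resolve why — the mobility of a
side CH2 group is ordered by its *topological distance* (number of
chemical bonds) to the end of its side segment, not by the spacer's
chemical identity — and provide every post-processing stage needed to
show it from trajectory data:

* **structure** — radius of gyration `Rg² = (1/M)Σ mᵢrᵢ²` and its
  pulsation ACF, gyration-tensor asphericity α, Kirkwood hydrodynamic
  radius `Rh = ⟨rᵢⱼ⁻¹⟩⁻¹`, terminal-group radius Re vs √(5/3)·Rg, radial
  density/terminal profiles ρ(r), n_t(r), congregation coefficient k45;
* **electrostatics** — radial charge q(r), cumulative Q(r), effective
  charge Q* at Rmax, σ = Q*/(4πRmax²), Q*/Qbare, Bjerrum length, the
  spherical Poisson solve for ψ(r) and the ζ potential at the slip plane,
  ion-pair counting from g(r) and the osmotic-ion balance
  ⟨n_osm⟩ = Qbare − Q* − ⟨n_pairs⟩;
* **hbonds** — geometric detection (D–A < 0.35 nm, H–D–A deviation
  < 30°), per-class counts, and continuous lifetimes with cubic-spline
  sub-frame refinement;
* **nmr** — P1/P2 orientational ACFs, 1/e times, spectral density
  J(ω) = 2∫P2(t)cos ωt dt, reduced rate ω[J(ω)+4J(2ω)], and physical
  1/T1H = (A0/ωH)·reduced at the 400 MHz spectrometer frequency;
* **synthetic** — generators with analytically known ground truth
  (isotropic rotational diffusion, Ornstein–Uhlenbeck size pulsation, a
  double-layer charge cloud, telegraph bond processes, and a Brownian
  coarse-grained dendrimer integrator) standing in for microsecond
  atomistic trajectories.

Standard formats (PDB/GRO + XTC/TRR/DCD) are read and written through
MDAnalysis; see `docs/methods.md` for the models, defaults and
numerical choices.

## Worked example

Build the second-generation Lys-2Arg topology and check its bookkeeping:

```python
>>> from dendromd.system import build_toy_dendrimer
>>> s = build_toy_dendrimer(2, "2Arg")
>>> s.nend, s.nins, s.bare_charge
(16, 28, 44)
```

16 terminal NH3+ sites and 28 charged spacer residues give the bare
charge +44 e, neutralised by 44 counterions.

Run the NMR chain on vector classes assigned per topological distance
(`python analysis/06_nmr_relaxation.py`):

```
spacer  n_bonds_to_end  tau_p2_ps  tau_truth_ps  reduced_rate  rate_1_T1H_s
  2Lys               1   2.075655      2.083333      0.051089      0.113835
  2Lys               2   4.184453      4.166667      0.104552      0.232960
  2Arg               3   8.407230      8.333333      0.208644      0.464894
  2Lys               3   8.307558      8.333333      0.201803      0.449650
  2Arg               4  16.699423     16.666667      0.431121      0.960610
  2Lys               4  16.308149     16.666667      0.403191      0.898378
  2Arg               5  31.293555     33.333333      0.798662      1.779554
```

Each class's P2 decay time matches its ground truth 1/(6·Dr) within a few
percent, the classes shared by both chemistries (3 and 4 bonds) coincide,
and within each dendrimer the time — and hence 1/T1H at the spectrometer
frequency — grows with the bond distance to the segment end.  The
NMR-active group sits 3 bonds from the end in a 2Arg spacer but only 1
bond in a 2Lys spacer, which is the whole difference between their
relaxation signatures.

The numbered scripts under `analysis/` run the full chain: topology
bookkeeping (01), Brownian toy trajectories (02), structural descriptors
(03), the electrostatic double layer against its closed form (04),
hydrogen-bond counts and lifetime validation (05), and the NMR mechanism
(06).  Each writes CSV tables under `results/`.

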