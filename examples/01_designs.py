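"""Design-space sampling: Latin-hypercube initialization and the
face-centered factorial design.

The six-variable space covers amine/DBU loading, concentration, residence
time, temperature and catalyst loading; the narrowed four-variable space
fixes residence time and concentration for the response-surface stage.
"""

from slugflow import default_doe_space, default_selfopt_space, face_centered_design, sample_lhc
from slugflow.design_space import design_to_frame

space6 = default_selfopt_space()
lhc = sample_lhc(space6, 2 * space6.n, seed=7)
print(f"LHC initialization: {len(lhc)} points (2n for n = {space6.n} variables)")
print(design_to_frame(space6, lhc).head(3).round(3).to_string(index=False))

space4 = default_doe_space()
design = face_centered_design(space4, n_center=6)
print(f"\nFace-centered design: {len(design)} runs "
      f"(2^4 = 16 corners + 2*4 = 8 faces + 6 center replicates)")
print(design_to_frame(space4, design).tail(3).round(3).to_string(index=False))
print("\nEach row is one reactor setpoint; coded_* columns are the -1..+1 "
      "units used by the response-surface model.")
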