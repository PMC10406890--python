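"""An ideal Bayesian observer learns to unmix two hidden sources.

Two binary sources are mixed into 32 binary inputs (each input carries its
dominant source with 75% probability).  A mean-field categorical/Dirichlet
observer watches 25600 fresh trials and learns the mixing probabilities
from scratch.
"""

import numpy as np

from neurofep import ExperimentDesign, StatePrior, generate_experiment
from neurofep.observer import posterior_mean_A, run_ideal_observer

design = ExperimentDesign(seed=1, repeat_identical_sequence=False)
sources, stimuli, A = generate_experiment(design)

traj = run_ideal_observer(stimuli, StatePrior(), schedule="per_session")
A_hat = posterior_mean_A(traj.a_final)

print("Posterior mixing probabilities after 25600 trials")
print("  left inputs,  P(on | s=(1,0)):",
      f"{A_hat[:16, 1, 1, 0].mean():.3f}  (designed: 0.75)")
print("  right inputs, P(on | s=(1,0)):",
      f"{A_hat[16:, 1, 1, 0].mean():.3f}  (designed: 0.25)")
print("  worst cell error vs the generative tensor:",
      f"{np.abs(A_hat - A.entries).max():.3f}")

last = slice(-2560, None)
r = np.corrcoef(traj.p_on[last, 0], sources[last, 0])[0, 1]
print(f"  correlation of the source-1 posterior with the true source: {r:.3f}")
print("A correlation near 1 means the observer has solved the blind "
      "source separation problem; cell errors ~0.01 reflect sampling noise.")
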