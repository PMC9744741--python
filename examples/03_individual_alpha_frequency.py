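"""Detect the individual alpha frequency (IAF) from eyes-closed spectra.

The IAF is the dominant peak of the occipital-average eyes-closed spectrum in
7-13 Hz; a maximum at the search boundary is flagged as not a true peak.
Here the detected values are compared with each subject's generative truth.
"""
from neurogaze import (CohortSpec, make_cohort, make_montage, synth_eeg,
                       welch_psd, detect_iaf)

montage = make_montage(64)
cohort = make_cohort(CohortSpec(seed=3, n_static=3, n_dynamic=3))
print("subject   group    true IAF  detected  true peak?")
for sub in cohort:
    rec = synth_eeg(sub, montage, "eyes_closed", duration_s=120.0, fs=250.0,
                    seed=3)
    res = detect_iaf(welch_psd(rec), montage)
    print(f"{sub.subject_id}   {sub.group:>8}   {sub.iaf_true:5.2f} Hz  "
          f"{res.iaf:5.2f} Hz   {res.is_true_peak}")
print("\nDetected values land on the 0.5 Hz Welch grid, so they match the"
      "\ncontinuous ground truth to within half a bin.")
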