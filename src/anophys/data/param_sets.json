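{
 "version": 1,
 "note": "Named generative parameter sets. Threshold-curve anchors come from measured population means; detection offsets, conductance scales, the calibrated anion permeability and the scrambling onset correction are written by scripts/calibrate.py.",
 "thermal_voltage_mV": 25.43,
 "permeation": {
  "nonselective": {
   "temperature_c": 22.0,
   "ions": [
    {
     "name": "Na",
     "z": 1,
     "in_mM": 0.0,
     "out_mM": 140.0,
     "p": 1.0
    },
    {
     "name": "Cs",
     "z": 1,
     "in_mM": 130.0,
     "out_mM": 0.0,
     "p": 1.0
    },
    {
     "name": "K",
     "z": 1,
     "in_mM": 0.0,
     "out_mM": 5.0,
     "p": 1.0
    },
    {
     "name": "Cl",
     "z": -1,
     "in_mM": 136.0,
     "out_mM": 140.0,
     "p": 1.0
    }
   ]
  },
  "nonselective_calibrated": {
   "temperature_c": 22.0,
   "ions": [
    {
     "name": "Na",
     "z": 1,
     "in_mM": 0.0,
     "out_mM": 140.0,
     "p": 1.0
    },
    {
     "name": "Cs",
     "z": 1,
     "in_mM": 130.0,
     "out_mM": 0.0,
     "p": 1.0
    },
    {
     "name": "K",
     "z": 1,
     "in_mM": 0.0,
     "out_mM": 5.0,
     "p": 1.0
    },
    {
     "name": "Cl",
     "z": -1,
     "in_mM": 136.0,
     "out_mM": 140.0,
     "p": 0.4684
    }
   ]
  },
  "anion_selective": {
   "temperature_c": 22.0,
   "ions": [
    {
     "name": "Cl",
     "z": -1,
     "in_mM": 136.0,
     "out_mM": 140.0,
     "p": 1.0
    }
   ]
  }
 },
 "baths": {
  "standard": {
   "Na": 140.0,
   "Cl": 140.0
  },
  "low_nacl": {
   "Na": 10.0,
   "Cl": 10.0
  }
 },
 "gating": {
  "WT-CHO": {
   "gmax": 1.094,
   "v_half_max_mV": 127.0,
   "delta_v_mV": 65.0,
   "slope_mV": 14.0,
   "ec50_um": 2.9,
   "hill": 1.5,
   "tau_ms": 60.0,
   "leak_ns": 0.5,
   "noise_sd_pA": 10.0,
   "cap_amp_pA": 500.0,
   "cap_tau_ms": 0.5,
   "detection_offset_mV": 40.01,
   "midpoint_sd_mV": 13.2,
   "conductance_cv": 0.3
  },
  "WT-CHO-anchored": {
   "gmax": 1.0639,
   "v_half_max_mV": 108.33,
   "delta_v_mV": 65.0,
   "slope_mV": 14.0,
   "ec50_um": 2.9,
   "hill": 1.5,
   "tau_ms": 60.0,
   "leak_ns": 0.5,
   "noise_sd_pA": 10.0,
   "cap_amp_pA": 500.0,
   "cap_tau_ms": 0.5,
   "detection_offset_mV": 37.5,
   "midpoint_sd_mV": 8.8,
   "conductance_cv": 0.3
  },
  "WT-HEK": {
   "gmax": 1.0828,
   "v_half_max_mV": 125.2,
   "delta_v_mV": 72.36,
   "slope_mV": 14.0,
   "ec50_um": 2.9,
   "hill": 1.5,
   "tau_ms": 60.0,
   "leak_ns": 0.5,
   "noise_sd_pA": 10.0,
   "cap_amp_pA": 500.0,
   "cap_tau_ms": 0.5,
   "detection_offset_mV": 40.78,
   "midpoint_sd_mV": 15.6,
   "conductance_cv": 0.3
  },
  "WT-913": {
   "gmax": 0.3492,
   "v_half_max_mV": 151.63,
   "delta_v_mV": 65.0,
   "slope_mV": 14.0,
   "ec50_um": 2.9,
   "hill": 1.5,
   "tau_ms": 60.0,
   "leak_ns": 0.5,
   "noise_sd_pA": 10.0,
   "cap_amp_pA": 500.0,
   "cap_tau_ms": 0.5,
   "detection_offset_mV": 29.84,
   "midpoint_sd_mV": 19.9,
   "conductance_cv": 0.3
  },
  "T498I": {
   "gmax": 0.8418,
   "v_half_max_mV": 82.3,
   "delta_v_mV": 39.3,
   "slope_mV": 14.0,
   "ec50_um": 2.4345,
   "hill": 1.5,
   "tau_ms": 60.0,
   "leak_ns": 0.5,
   "noise_sd_pA": 10.0,
   "cap_amp_pA": 500.0,
   "cap_tau_ms": 0.5,
   "detection_offset_mV": 33.01,
   "midpoint_sd_mV": 13.6,
   "conductance_cv": 0.3
  },
  "TMEM16B-like": {
   "gmax": 2.7832,
   "v_half_max_mV": 150.0,
   "delta_v_mV": 120.0,
   "slope_mV": 14.0,
   "ec50_um": 1.8,
   "hill": 2.0,
   "tau_ms": 60.0,
   "leak_ns": 0.5,
   "noise_sd_pA": 10.0,
   "cap_amp_pA": 500.0,
   "cap_tau_ms": 0.5,
   "detection_offset_mV": 39.69,
   "midpoint_sd_mV": 10.0,
   "conductance_cv": 0.3
  },
  "control": {
   "gmax": 0.0,
   "v_half_max_mV": 127.0,
   "delta_v_mV": 65.0,
   "slope_mV": 14.0,
   "ec50_um": 2.9,
   "hill": 1.5,
   "tau_ms": 60.0,
   "leak_ns": 1.0,
   "noise_sd_pA": 10.0,
   "cap_amp_pA": 500.0,
   "cap_tau_ms": 0.5,
   "detection_offset_mV": 0.0,
   "midpoint_sd_mV": 0.0,
   "conductance_cv": 0.0
  }
 },
 "scrambling": {
  "latency_loc_min": 5.0247,
  "latency_sd_min": 2.214,
  "latency_lo_min": 1.0,
  "latency_hi_min": 22.0,
  "rise_tau_min": 6.0,
  "plateau_au": 1000.0,
  "plateau_cv": 0.25,
  "background_au": 100.0,
  "drift_au_per_min": 0.1,
  "noise_sd_au": 10.0,
  "sampling_min": 1.0,
  "duration_min": 25.0,
  "criterion_sd": 3.0,
  "sustain_samples": 2,
  "floor_norm": 0.01,
  "baseline_samples": 5,
  "onset_correction_min": 0.697
 }
}
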