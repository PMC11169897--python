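{
 "note": "Printed feature values of the cathode-array far-field study; 453-nm absorptances for gaps other than 1.5 nm are synthetic anchors from a Lorentzian lineshape (coupled-dipole resonance position and halfwidth) scaled to the printed peak heights.",
 "gaps": {
  "1": {
   "peak_wavelength_nm": 462.0,
   "resonance_halfwidth_nm": 163.0,
   "anchors": [
    {
     "wavelength_nm": 462.0,
     "absorptance": 0.68,
     "reflectance": 0.1,
     "transmittance": 0.22
    },
    {
     "wavelength_nm": 453.0,
     "absorptance": 0.6779
    }
   ]
  },
  "1.5": {
   "peak_wavelength_nm": 453.0,
   "resonance_halfwidth_nm": 153.0,
   "anchors": [
    {
     "wavelength_nm": 453.0,
     "absorptance": 0.65,
     "reflectance": 0.15,
     "transmittance": 0.2,
     "c_abs_nm2": 1500.0
    }
   ]
  },
  "2.5": {
   "peak_wavelength_nm": 438.0,
   "resonance_halfwidth_nm": 138.0,
   "anchors": [
    {
     "wavelength_nm": 438.0,
     "absorptance": 0.58,
     "reflectance": 0.22,
     "transmittance": 0.2
    },
    {
     "wavelength_nm": 453.0,
     "absorptance": 0.5732
    }
   ]
  },
  "5": {
   "peak_wavelength_nm": 413.0,
   "resonance_halfwidth_nm": 113.0,
   "anchors": [
    {
     "wavelength_nm": 413.0,
     "absorptance": 0.5,
     "reflectance": 0.32,
     "transmittance": 0.18
    },
    {
     "wavelength_nm": 453.0,
     "absorptance": 0.4443
    }
   ]
  }
 }
}
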