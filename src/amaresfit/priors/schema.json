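{
 "$defs": {
  "Multiplet": {
   "description": "J-coupling multiplet structure of a peak.\n\n``n_components`` components are placed symmetrically about the parent\nshift at spacings of ``j_hz`` (doublet at -J/2, +J/2; triplet at\n-J, 0, +J) with amplitudes ``amplitude_ratios[i] * free_amplitude``.",
   "properties": {
    "n_components": {
     "minimum": 2,
     "title": "N Components",
     "type": "integer"
    },
    "j_hz": {
     "exclusiveMinimum": 0.0,
     "title": "J Hz",
     "type": "number"
    },
    "amplitude_ratios": {
     "anyOf": [
      {
       "items": {
        "type": "number"
       },
       "type": "array"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Amplitude Ratios"
    }
   },
   "required": [
    "n_components",
    "j_hz"
   ],
   "title": "Multiplet",
   "type": "object"
  }
 },
 "description": "Bounds, starting values and relationships for one named peak.\n\nQuantities: shift in ppm, linewidth in Hz FWHM, amplitude in signal\nunits, phase in degrees.  ``lower == upper`` fixes a quantity (it is\nremoved from the free parameters).  Group ids are arbitrary strings;\nall peaks naming the same id share one free parameter for that\nquantity.  ``phase_offset``/``shift_offset`` are additive constants\nrelative to the group value and require the matching group field.",
 "properties": {
  "name": {
   "title": "Name",
   "type": "string"
  },
  "shift_start": {
   "title": "Shift Start",
   "type": "number"
  },
  "shift_lower": {
   "anyOf": [
    {
     "type": "number"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Shift Lower"
  },
  "shift_upper": {
   "anyOf": [
    {
     "type": "number"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Shift Upper"
  },
  "linewidth_start": {
   "default": 10.0,
   "title": "Linewidth Start",
   "type": "number"
  },
  "linewidth_lower": {
   "default": 1.0,
   "title": "Linewidth Lower",
   "type": "number"
  },
  "linewidth_upper": {
   "default": 100.0,
   "title": "Linewidth Upper",
   "type": "number"
  },
  "amplitude_start": {
   "default": 1.0,
   "title": "Amplitude Start",
   "type": "number"
  },
  "amplitude_lower": {
   "default": 0.0,
   "title": "Amplitude Lower",
   "type": "number"
  },
  "amplitude_upper": {
   "default": Infinity,
   "title": "Amplitude Upper",
   "type": "number"
  },
  "phase_start": {
   "default": 0.0,
   "title": "Phase Start",
   "type": "number"
  },
  "phase_lower": {
   "default": -180.0,
   "title": "Phase Lower",
   "type": "number"
  },
  "phase_upper": {
   "default": 180.0,
   "title": "Phase Upper",
   "type": "number"
  },
  "lineshape_g": {
   "default": 0.0,
   "maximum": 1.0,
   "minimum": 0.0,
   "title": "Lineshape G",
   "type": "number"
  },
  "multiplet": {
   "anyOf": [
    {
     "$ref": "#/$defs/Multiplet"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "group_linewidth": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Group Linewidth"
  },
  "group_amplitude": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Group Amplitude"
  },
  "group_phase": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Group Phase"
  },
  "group_shift": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Group Shift"
  },
  "amplitude_ratio": {
   "anyOf": [
    {
     "exclusiveMinimum": 0.0,
     "type": "number"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Amplitude Ratio"
  },
  "phase_offset": {
   "default": 0.0,
   "title": "Phase Offset",
   "type": "number"
  },
  "shift_offset": {
   "default": 0.0,
   "title": "Shift Offset",
   "type": "number"
  },
  "base_linewidth": {
   "default": 0.0,
   "title": "Base Linewidth",
   "type": "number"
  }
 },
 "required": [
  "name",
  "shift_start"
 ],
 "title": "PeakPrior",
 "type": "object"
}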