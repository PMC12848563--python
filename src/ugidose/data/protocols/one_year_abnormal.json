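{
 "age_class": "one_year",
 "diagnosis": "abnormal",
 "pulse_rate_hz": 7.5,
 "fields": [
  {
   "id": "1A",
   "projection": "PA",
   "fluoro_seconds": 10.0,
   "spot_film": true,
   "box": {
    "z_lo": [
     "colon",
     "lo",
     -1.0
    ],
    "z_hi": [
     "lungs",
     "hi",
     1.0
    ],
    "width_fraction": 0.95
   }
  },
  {
   "id": "2A",
   "projection": "PA",
   "fluoro_seconds": 10.0,
   "spot_film": false,
   "box": {
    "z_lo": [
     "si_wall",
     "mid",
     0.0
    ],
    "z_hi": [
     "stomach_wall",
     "hi",
     1.0
    ],
    "width_fraction": 0.7
   }
  },
  {
   "id": "3A",
   "projection": "right-lateral",
   "fluoro_seconds": 10.0,
   "spot_film": true,
   "box": {
    "z_lo": [
     "si_wall",
     "lo",
     -0.5
    ],
    "z_hi": [
     "stomach_wall",
     "hi",
     0.5
    ],
    "width_fraction": 0.7
   },
   "contrast": {
    "stomach_contents": [
     [
      "omnipaque_140",
      1.0
     ]
    ],
    "si_contents": [
     [
      "omnipaque_140",
      0.1
     ],
     [
      "__base__",
      0.9
     ]
    ]
   }
  },
  {
   "id": "4A",
   "projection": "right-lateral",
   "fluoro_seconds": 15.0,
   "spot_film": true,
   "box": {
    "z_lo": [
     "si_wall",
     "lo",
     -0.5
    ],
    "z_hi": [
     "stomach_wall",
     "hi",
     0.5
    ],
    "width_fraction": 0.7
   },
   "contrast": {
    "stomach_contents": [
     [
      "omnipaque_140",
      0.8
     ],
     [
      "__base__",
      0.2
     ]
    ],
    "si_contents": [
     [
      "omnipaque_140",
      0.3
     ],
     [
      "__base__",
      0.7
     ]
    ]
   }
  },
  {
   "id": "5A",
   "projection": "PA",
   "fluoro_seconds": 20.0,
   "spot_film": true,
   "box": {
    "z_lo": [
     "si_wall",
     "lo",
     -0.5
    ],
    "z_hi": [
     "stomach_wall",
     "hi",
     0.5
    ],
    "width_fraction": 0.75
   },
   "contrast": {
    "stomach_contents": [
     [
      "omnipaque_140",
      0.8
     ],
     [
      "__base__",
      0.2
     ]
    ],
    "si_contents": [
     [
      "omnipaque_140",
      0.3
     ],
     [
      "__base__",
      0.7
     ]
    ]
   }
  },
  {
   "id": "6A",
   "projection": "LPO15",
   "fluoro_seconds": 15.0,
   "spot_film": true,
   "box": {
    "z_lo": [
     "si_wall",
     "lo",
     -0.5
    ],
    "z_hi": [
     "stomach_wall",
     "mid",
     0.0
    ],
    "width_fraction": 0.6
   },
   "contrast": {
    "stomach_contents": [
     [
      "omnipaque_140",
      0.8
     ],
     [
      "__base__",
      0.2
     ]
    ],
    "si_contents": [
     [
      "omnipaque_140",
      0.3
     ],
     [
      "__base__",
      0.7
     ]
    ]
   }
  },
  {
   "id": "7A",
   "projection": "RPO15",
   "fluoro_seconds": 15.0,
   "spot_film": true,
   "box": {
    "z_lo": [
     "si_wall",
     "lo",
     -0.5
    ],
    "z_hi": [
     "stomach_wall",
     "mid",
     0.0
    ],
    "width_fraction": 0.6
   },
   "contrast": {
    "stomach_contents": [
     [
      "omnipaque_140",
      0.8
     ],
     [
      "__base__",
      0.2
     ]
    ],
    "si_contents": [
     [
      "omnipaque_140",
      0.3
     ],
     [
      "__base__",
      0.7
     ]
    ]
   }
  }
 ]
}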