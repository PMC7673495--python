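{
 "name_location_lr": {
  "per_class": {
   "Ab": [
    0.82,
    1.0,
    0.86,
    1.0,
    0.84,
    0.99
   ],
   "Ch": [
    0.92,
    1.0,
    0.95,
    1.0,
    0.94,
    1.0
   ],
   "En": [
    0.76,
    0.86,
    0.64,
    0.92,
    0.69,
    0.94
   ],
   "Fr": [
    0.95,
    0.97,
    0.94,
    0.98,
    0.95,
    0.97
   ],
   "Ir": [
    0.61,
    0.93,
    0.67,
    0.91,
    0.64,
    0.87
   ],
   "It": [
    0.57,
    1.0,
    0.83,
    1.0,
    0.67,
    1.0
   ],
   "Jp": [
    0.86,
    1.0,
    0.94,
    1.0,
    0.9,
    1.0
   ],
   "Others": [
    0.59,
    0.98,
    0.74,
    0.96,
    0.66,
    0.95
   ],
   "Ru": [
    0.78,
    1.0,
    0.91,
    1.0,
    0.84,
    1.0
   ],
   "Sc": [
    0.63,
    0.95,
    0.7,
    0.94,
    0.66,
    0.9
   ]
  },
  "overall": [
   0.76,
   0.94,
   0.76,
   0.94,
   0.76,
   0.91
  ]
 },
 "name_only_lr": {
  "per_class": {
   "Ab": [
    0.38,
    1.0,
    0.76,
    0.99,
    0.5,
    0.99
   ],
   "Ch": [
    0.89,
    1.0,
    0.94,
    1.0,
    0.92,
    1.0
   ],
   "En": [
    0.74,
    0.83,
    0.59,
    0.91,
    0.65,
    0.81
   ],
   "Fr": [
    0.94,
    0.96,
    0.91,
    0.97,
    0.93,
    0.95
   ],
   "Ir": [
    0.54,
    0.93,
    0.63,
    0.9,
    0.58,
    0.85
   ],
   "It": [
    0.49,
    1.0,
    0.8,
    1.0,
    0.61,
    1.0
   ],
   "Jp": [
    0.72,
    1.0,
    0.87,
    1.0,
    0.79,
    1.0
   ],
   "Others": [
    0.54,
    0.98,
    0.7,
    0.96,
    0.61,
    0.94
   ],
   "Ru": [
    0.67,
    1.0,
    0.88,
    1.0,
    0.76,
    1.0
   ],
   "Sc": [
    0.6,
    0.95,
    0.66,
    0.93,
    0.63,
    0.9
   ]
  },
  "overall": [
   0.72,
   0.92,
   0.72,
   0.94,
   0.71,
   0.89
  ]
 },
 "metric_order": [
  "sensitivity",
  "specificity",
  "ppv",
  "npv",
  "f1",
  "accuracy"
 ]
}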