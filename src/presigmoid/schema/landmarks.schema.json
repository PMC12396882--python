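{
 "$defs": {
  "_DiscModel": {
   "additionalProperties": false,
   "properties": {
    "center": {
     "maxItems": 3,
     "minItems": 3,
     "prefixItems": [
      {
       "type": "number"
      },
      {
       "type": "number"
      },
      {
       "type": "number"
      }
     ],
     "title": "Center",
     "type": "array"
    },
    "radius": {
     "exclusiveMinimum": 0,
     "title": "Radius",
     "type": "number"
    }
   },
   "required": [
    "center",
    "radius"
   ],
   "title": "_DiscModel",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "properties": {
  "schema_version": {
   "title": "Schema Version",
   "type": "string"
  },
  "units": {
   "default": "mm",
   "title": "Units",
   "type": "string"
  },
  "specimen_id": {
   "title": "Specimen Id",
   "type": "string"
  },
  "side": {
   "title": "Side",
   "type": "string"
  },
  "covering_thickness_mm": {
   "anyOf": [
    {
     "type": "number"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Covering Thickness Mm"
  },
  "P": {
   "maxItems": 3,
   "minItems": 3,
   "prefixItems": [
    {
     "type": "number"
    },
    {
     "type": "number"
    },
    {
     "type": "number"
    }
   ],
   "title": "P",
   "type": "array"
  },
  "iac_mid": {
   "maxItems": 3,
   "minItems": 3,
   "prefixItems": [
    {
     "type": "number"
    },
    {
     "type": "number"
    },
    {
     "type": "number"
    }
   ],
   "title": "Iac Mid",
   "type": "array"
  },
  "iac_anterolateral": {
   "maxItems": 3,
   "minItems": 3,
   "prefixItems": [
    {
     "type": "number"
    },
    {
     "type": "number"
    },
    {
     "type": "number"
    }
   ],
   "title": "Iac Anterolateral",
   "type": "array"
  },
  "ss_anterior_above_iac": {
   "maxItems": 3,
   "minItems": 3,
   "prefixItems": [
    {
     "type": "number"
    },
    {
     "type": "number"
    },
    {
     "type": "number"
    }
   ],
   "title": "Ss Anterior Above Iac",
   "type": "array"
  },
  "ss_cross_iac": {
   "$ref": "#/$defs/_DiscModel"
  },
  "ss_cross_bulb": {
   "$ref": "#/$defs/_DiscModel"
  },
  "ss_medial_border": {
   "maxItems": 3,
   "minItems": 3,
   "prefixItems": [
    {
     "type": "number"
    },
    {
     "type": "number"
    },
    {
     "type": "number"
    }
   ],
   "title": "Ss Medial Border",
   "type": "array"
  },
  "fn_cross_iac": {
   "$ref": "#/$defs/_DiscModel"
  },
  "fn_cross_bulb": {
   "$ref": "#/$defs/_DiscModel"
  },
  "sinodural_angle": {
   "maxItems": 3,
   "minItems": 3,
   "prefixItems": [
    {
     "type": "number"
    },
    {
     "type": "number"
    },
    {
     "type": "number"
    }
   ],
   "title": "Sinodural Angle",
   "type": "array"
  },
  "tegmen_points": {
   "items": {
    "maxItems": 3,
    "minItems": 3,
    "prefixItems": [
     {
      "type": "number"
     },
     {
      "type": "number"
     },
     {
      "type": "number"
     }
    ],
    "type": "array"
   },
   "minItems": 3,
   "title": "Tegmen Points",
   "type": "array"
  },
  "jugular_bulb_top": {
   "maxItems": 3,
   "minItems": 3,
   "prefixItems": [
    {
     "type": "number"
    },
    {
     "type": "number"
    },
    {
     "type": "number"
    }
   ],
   "title": "Jugular Bulb Top",
   "type": "array"
  },
  "craniotomy_rim": {
   "items": {
    "maxItems": 3,
    "minItems": 3,
    "prefixItems": [
     {
      "type": "number"
     },
     {
      "type": "number"
     },
     {
      "type": "number"
     }
    ],
    "type": "array"
   },
   "minItems": 6,
   "title": "Craniotomy Rim",
   "type": "array"
  },
  "anterior_rim_point": {
   "maxItems": 3,
   "minItems": 3,
   "prefixItems": [
    {
     "type": "number"
    },
    {
     "type": "number"
    },
    {
     "type": "number"
    }
   ],
   "title": "Anterior Rim Point",
   "type": "array"
  },
  "dura_posterior_ss": {
   "maxItems": 3,
   "minItems": 3,
   "prefixItems": [
    {
     "type": "number"
    },
    {
     "type": "number"
    },
    {
     "type": "number"
    }
   ],
   "title": "Dura Posterior Ss",
   "type": "array"
  },
  "presigmoid_dura_sup": {
   "maxItems": 3,
   "minItems": 3,
   "prefixItems": [
    {
     "type": "number"
    },
    {
     "type": "number"
    },
    {
     "type": "number"
    }
   ],
   "title": "Presigmoid Dura Sup",
   "type": "array"
  },
  "presigmoid_dura_inf": {
   "maxItems": 3,
   "minItems": 3,
   "prefixItems": [
    {
     "type": "number"
    },
    {
     "type": "number"
    },
    {
     "type": "number"
    }
   ],
   "title": "Presigmoid Dura Inf",
   "type": "array"
  }
 },
 "required": [
  "schema_version",
  "specimen_id",
  "side",
  "P",
  "iac_mid",
  "iac_anterolateral",
  "ss_anterior_above_iac",
  "ss_cross_iac",
  "ss_cross_bulb",
  "ss_medial_border",
  "fn_cross_iac",
  "fn_cross_bulb",
  "sinodural_angle",
  "tegmen_points",
  "jugular_bulb_top",
  "craniotomy_rim",
  "anterior_rim_point",
  "dura_posterior_ss",
  "presigmoid_dura_sup",
  "presigmoid_dura_inf"
 ],
 "title": "presigmoid specimen landmark file",
 "type": "object",
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "version": "1.0"
}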