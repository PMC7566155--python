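{
 "$defs": {
  "ArcModel": {
   "properties": {
    "child": {
     "title": "Child",
     "type": "string"
    },
    "parents": {
     "items": {
      "type": "string"
     },
     "title": "Parents",
     "type": "array"
    }
   },
   "required": [
    "child",
    "parents"
   ],
   "title": "ArcModel",
   "type": "object"
  },
  "TableModel": {
   "properties": {
    "variable": {
     "title": "Variable",
     "type": "string"
    },
    "parent_config": {
     "additionalProperties": {
      "type": "string"
     },
     "default": {},
     "title": "Parent Config",
     "type": "object"
    },
    "lower": {
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
     "title": "Lower"
    },
    "upper": {
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
     "title": "Upper"
    },
    "orderings": {
     "default": [],
     "items": {
      "maxItems": 2,
      "minItems": 2,
      "prefixItems": [
       {
        "type": "string"
       },
       {
        "type": "string"
       }
      ],
      "type": "array"
     },
     "title": "Orderings",
     "type": "array"
    },
    "judgments": {
     "default": [],
     "items": {
      "additionalProperties": true,
      "type": "object"
     },
     "title": "Judgments",
     "type": "array"
    },
    "provenance": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Provenance"
    }
   },
   "required": [
    "variable"
   ],
   "title": "TableModel",
   "type": "object"
  },
  "VariableModel": {
   "properties": {
    "name": {
     "title": "Name",
     "type": "string"
    },
    "states": {
     "items": {
      "type": "string"
     },
     "minItems": 2,
     "title": "States",
     "type": "array"
    }
   },
   "required": [
    "name",
    "states"
   ],
   "title": "VariableModel",
   "type": "object"
  }
 },
 "properties": {
  "name": {
   "default": "",
   "title": "Name",
   "type": "string"
  },
  "description": {
   "default": "",
   "title": "Description",
   "type": "string"
  },
  "table_defaults": {
   "additionalProperties": {
    "type": "string"
   },
   "default": {},
   "title": "Table Defaults",
   "type": "object"
  },
  "variables": {
   "items": {
    "$ref": "#/$defs/VariableModel"
   },
   "minItems": 1,
   "title": "Variables",
   "type": "array"
  },
  "arcs": {
   "default": [],
   "items": {
    "$ref": "#/$defs/ArcModel"
   },
   "title": "Arcs",
   "type": "array"
  },
  "tables": {
   "default": [],
   "items": {
    "$ref": "#/$defs/TableModel"
   },
   "title": "Tables",
   "type": "array"
  }
 },
 "required": [
  "variables"
 ],
 "title": "NetworkModel",
 "type": "object"
}
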