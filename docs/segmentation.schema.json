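{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "segff segmentation (JSON encoding)",
 "type": "object",
 "required": ["schemaVersion", "transformList", "latticeList", "segmentList"],
 "properties": {
  "schemaVersion": {"type": "string", "minLength": 1},
  "name": {"type": "string"},
  "details": {"type": "string"},
  "softwareList": {
   "type": "array",
   "items": {
    "type": "object",
    "properties": {
     "name": {"type": "string"},
     "version": {"type": "string"},
     "processingDetails": {"type": "string"}
    }
   }
  },
  "boundingBox": {
   "type": "object",
   "required": ["xmin", "xmax", "ymin", "ymax", "zmin", "zmax"],
   "properties": {
    "xmin": {"type": "number"}, "xmax": {"type": "number"},
    "ymin": {"type": "number"}, "ymax": {"type": "number"},
    "zmin": {"type": "number"}, "zmax": {"type": "number"}
   }
  },
  "globalExternalReferences": {
   "type": "array", "items": {"$ref": "#/$defs/externalReference"}
  },
  "transformList": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "matrix"],
    "properties": {
     "id": {"type": "integer", "minimum": 0},
     "matrix": {
      "type": "array", "items": {"type": "number"},
      "minItems": 12, "maxItems": 12
     }
    }
   }
  },
  "latticeList": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "size", "runs"],
    "properties": {
     "id": {"type": "integer", "minimum": 0},
     "mode": {"enum": ["u1", "u8", "u16", "u32"]},
     "size": {"type": "array", "items": {"type": "integer", "minimum": 1},
              "minItems": 3, "maxItems": 3},
     "origin": {"type": "array", "items": {"type": "integer"},
                "minItems": 3, "maxItems": 3},
     "voxelSize": {"type": "array", "items": {"type": "number"},
                   "minItems": 3, "maxItems": 3},
     "runs": {"type": "array", "items": {"type": "integer", "minimum": 0}}
    }
   }
  },
  "segmentList": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "parentId"],
    "properties": {
     "id": {"type": "integer", "minimum": 1},
     "parentId": {"type": "integer", "minimum": 0},
     "name": {"type": "string"},
     "colour": {
      "type": "object",
      "required": ["r", "g", "b"],
      "properties": {
       "r": {"type": "number", "minimum": 0, "maximum": 1},
       "g": {"type": "number", "minimum": 0, "maximum": 1},
       "b": {"type": "number", "minimum": 0, "maximum": 1},
       "a": {"type": "number", "minimum": 0, "maximum": 1}
      }
     },
     "biologicalAnnotation": {
      "type": "object",
      "properties": {
       "name": {"type": "string"},
       "description": {"type": "string"},
       "numberOfInstances": {"type": "integer", "minimum": 1},
       "externalReferences": {
        "type": "array", "items": {"$ref": "#/$defs/externalReference"}
       }
      }
     },
     "meshList": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["vertices", "triangles"],
       "properties": {
        "vertices": {"type": "array", "items": {"type": "number"}},
        "normals": {"type": "array", "items": {"type": "number"}},
        "triangles": {"type": "array",
                      "items": {"type": "integer", "minimum": 0}},
        "transformId": {"type": "integer", "minimum": 0}
       }
      }
     },
     "volumeRef": {
      "type": "object",
      "properties": {
       "latticeId": {"type": "integer", "minimum": 0},
       "voxelValue": {"type": "integer", "minimum": 0},
       "externalPath": {"type": "string"}
      }
     },
     "shapePrimitiveList": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["kind", "parameters"],
       "properties": {
        "kind": {"enum": ["sphere", "ellipsoid", "cuboid", "cylinder"]},
        "parameters": {"type": "array", "items": {"type": "number"}},
        "transformId": {"type": "integer", "minimum": 0}
       }
      }
     },
     "contourList": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["points"],
       "properties": {
        "points": {"type": "array", "items": {"type": "number"}},
        "closed": {"type": "boolean"}
       }
      }
     },
     "transformIds": {
      "type": "array", "items": {"type": "integer", "minimum": 0}
     }
    }
   }
  }
 },
 "$defs": {
  "externalReference": {
   "type": "object",
   "required": ["resource", "accession"],
   "properties": {
    "resource": {"type": "string", "minLength": 1},
    "accession": {"type": "string", "minLength": 1},
    "label": {"type": "string"},
    "description": {"type": "string"},
    "url": {"type": "string"}
   }
  }
 }
}
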