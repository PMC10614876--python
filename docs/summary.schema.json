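{
 "$defs": {
  "FragmentRecord": {
   "properties": {
    "query_start": {
     "minimum": 1,
     "title": "Query Start",
     "type": "integer"
    },
    "query_end": {
     "minimum": 1,
     "title": "Query End",
     "type": "integer"
    },
    "target_start": {
     "minimum": 1,
     "title": "Target Start",
     "type": "integer"
    },
    "target_end": {
     "minimum": 1,
     "title": "Target End",
     "type": "integer"
    },
    "evalue": {
     "minimum": 0,
     "title": "Evalue",
     "type": "number"
    },
    "score": {
     "title": "Score",
     "type": "number"
    }
   },
   "required": [
    "query_start",
    "query_end",
    "target_start",
    "target_end",
    "evalue",
    "score"
   ],
   "title": "FragmentRecord",
   "type": "object"
  },
  "GenomeSummary": {
   "properties": {
    "integrations": {
     "items": {
      "$ref": "#/$defs/IntegrationRecord"
     },
     "title": "Integrations",
     "type": "array"
    }
   },
   "required": [
    "integrations"
   ],
   "title": "GenomeSummary",
   "type": "object"
  },
  "IntegrationRecord": {
   "properties": {
    "id": {
     "title": "Id",
     "type": "string"
    },
    "phage": {
     "title": "Phage",
     "type": "string"
    },
    "start": {
     "description": "genome span start, 1-based inclusive",
     "minimum": 1,
     "title": "Start",
     "type": "integer"
    },
    "end": {
     "minimum": 1,
     "title": "End",
     "type": "integer"
    },
    "strand": {
     "pattern": "^[+-]$",
     "title": "Strand",
     "type": "string"
    },
    "full_length": {
     "title": "Full Length",
     "type": "boolean"
    },
    "query_coverage_nt": {
     "minimum": 1,
     "title": "Query Coverage Nt",
     "type": "integer"
    },
    "fragments": {
     "items": {
      "$ref": "#/$defs/FragmentRecord"
     },
     "title": "Fragments",
     "type": "array"
    }
   },
   "required": [
    "id",
    "phage",
    "start",
    "end",
    "strand",
    "full_length",
    "query_coverage_nt",
    "fragments"
   ],
   "title": "IntegrationRecord",
   "type": "object"
  },
  "QueryExtent": {
   "description": "Extent of one integration on the query phage it matched.",
   "properties": {
    "id": {
     "title": "Id",
     "type": "string"
    },
    "genome": {
     "title": "Genome",
     "type": "string"
    },
    "query_start": {
     "minimum": 1,
     "title": "Query Start",
     "type": "integer"
    },
    "query_end": {
     "minimum": 1,
     "title": "Query End",
     "type": "integer"
    }
   },
   "required": [
    "id",
    "genome",
    "query_start",
    "query_end"
   ],
   "title": "QueryExtent",
   "type": "object"
  },
  "QuerySummary": {
   "properties": {
    "length": {
     "minimum": 1,
     "title": "Length",
     "type": "integer"
    },
    "counts": {
     "items": {
      "type": "integer"
     },
     "title": "Counts",
     "type": "array"
    },
    "integrations": {
     "items": {
      "$ref": "#/$defs/QueryExtent"
     },
     "title": "Integrations",
     "type": "array"
    }
   },
   "required": [
    "length",
    "counts",
    "integrations"
   ],
   "title": "QuerySummary",
   "type": "object"
  }
 },
 "properties": {
  "schema_version": {
   "title": "Schema Version",
   "type": "string"
  },
  "genomes": {
   "additionalProperties": {
    "$ref": "#/$defs/GenomeSummary"
   },
   "title": "Genomes",
   "type": "object"
  },
  "queries": {
   "additionalProperties": {
    "$ref": "#/$defs/QuerySummary"
   },
   "title": "Queries",
   "type": "object"
  }
 },
 "required": [
  "schema_version",
  "genomes",
  "queries"
 ],
 "title": "RunSummary",
 "type": "object"
}
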