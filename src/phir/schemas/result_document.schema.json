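{
 "description": "One search result as served to external applications; all fields are\nalways present, lists may be empty.",
 "properties": {
  "doc_id": {
   "title": "Doc Id",
   "type": "string"
  },
  "url": {
   "title": "Url",
   "type": "string"
  },
  "title": {
   "title": "Title",
   "type": "string"
  },
  "type": {
   "pattern": "^(text|video)$",
   "title": "Type",
   "type": "string"
  },
  "language": {
   "title": "Language",
   "type": "string"
  },
  "tags": {
   "items": {
    "type": "string"
   },
   "title": "Tags",
   "type": "array"
  },
  "concepts": {
   "items": {
    "type": "string"
   },
   "title": "Concepts",
   "type": "array"
  },
  "score": {
   "title": "Score",
   "type": "number"
  },
  "tier": {
   "maximum": 3,
   "minimum": 1,
   "title": "Tier",
   "type": "integer"
  },
  "rank": {
   "minimum": 1,
   "title": "Rank",
   "type": "integer"
  }
 },
 "required": [
  "doc_id",
  "url",
  "title",
  "type",
  "language",
  "tags",
  "concepts",
  "score",
  "tier",
  "rank"
 ],
 "title": "ResultDocumentJSON",
 "type": "object"
}
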