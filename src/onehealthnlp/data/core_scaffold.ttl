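# Core scaffold for the populated graphs: the semantic-type tree used by
# the query families (with part-of links to the group level), the lexicon
# and association class skeletons, and the six validation-label classes
# under stub evidence superclasses.

@prefix rdf:   <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs:  <http://www.w3.org/2000/01/rdf-schema#> .
@prefix owl:   <http://www.w3.org/2002/07/owl#> .
@prefix obo:   <http://purl.obolibrary.org/obo/> .
@prefix lemon: <http://lemon-model.net/lemon#> .
@prefix oban:  <http://purl.org/oban/> .
@prefix ustg:  <http://onehealthnlp.example.org/ustg#> .
@prefix kb:    <http://onehealthnlp.example.org/kb/> .

# --- lexicon skeleton ------------------------------------------------------

lemon:LexicalTopic a owl:Class ; rdfs:label "Lexical topic"@en .
lemon:Lexicon      a owl:Class ; rdfs:label "Lexicon"@en .
lemon:LexicalEntry a owl:Class ; rdfs:label "Lexical entry"@en .
lemon:LexicalSense a owl:Class ; rdfs:label "Lexical sense"@en .

# --- association skeleton --------------------------------------------------

oban:association a owl:Class ; rdfs:label "association"@en .
oban:provenance  a owl:Class ; rdfs:label "provenance"@en .
kb:Excerpt       a owl:Class ; rdfs:label "Excerpt"@en .

# --- semantic-type tree (query-relevant fragment) --------------------------

ustg:MetathesaurusConcept a owl:Class ; rdfs:label "Metathesaurus concept"@en .
ustg:SemanticType a owl:Class ;
    rdfs:label "Semantic type"@en ;
    rdfs:subClassOf lemon:LexicalSense .
ustg:SemanticGroup a owl:Class ; rdfs:label "Semantic group"@en .

ustg:T058 a owl:Class ; rdfs:subClassOf ustg:SemanticType ;
    rdfs:label "Health Care Activity"@en .
ustg:T059 a owl:Class ; rdfs:subClassOf ustg:T058 ;
    rdfs:label "Laboratory Procedure"@en ;
    obo:BFO_0000050 ustg:T058 .
ustg:T060 a owl:Class ; rdfs:subClassOf ustg:T058 ;
    rdfs:label "Diagnostic Procedure"@en ;
    obo:BFO_0000050 ustg:T058 .
ustg:T061 a owl:Class ; rdfs:subClassOf ustg:T058 ;
    rdfs:label "Therapeutic or Preventive Procedure"@en ;
    obo:BFO_0000050 ustg:T058 .

ustg:T033 a owl:Class ; rdfs:subClassOf ustg:SemanticType ;
    rdfs:label "Finding"@en .
ustg:T034 a owl:Class ; rdfs:subClassOf ustg:T033 ;
    rdfs:label "Laboratory or Test Result"@en ;
    obo:BFO_0000050 ustg:T033 .
ustg:T184 a owl:Class ; rdfs:subClassOf ustg:T033 ;
    rdfs:label "Sign or Symptom"@en ;
    obo:BFO_0000050 ustg:T033 .

ustg:T047 a owl:Class ; rdfs:subClassOf ustg:SemanticType ;
    rdfs:label "Disease or Syndrome"@en .

ustg:CHEM a owl:Class ; rdfs:subClassOf ustg:SemanticGroup ;
    rdfs:label "Chemicals & Drugs"@en .
ustg:T121 a owl:Class ; rdfs:subClassOf ustg:SemanticType ;
    rdfs:label "Pharmacologic Substance"@en ;
    obo:BFO_0000050 ustg:CHEM .
ustg:T109 a owl:Class ; rdfs:subClassOf ustg:SemanticType ;
    rdfs:label "Organic Chemical"@en ;
    obo:BFO_0000050 ustg:CHEM .
ustg:T116 a owl:Class ; rdfs:subClassOf ustg:SemanticType ;
    rdfs:label "Amino Acid, Peptide, or Protein"@en ;
    obo:BFO_0000050 ustg:CHEM .

# --- evidence stubs and validation labels ----------------------------------

kb:Evidence a owl:Class ; rdfs:label "Evidence"@en .
kb:SimilarityEvidence a owl:Class ; rdfs:subClassOf kb:Evidence .
kb:CurationEvidence   a owl:Class ; rdfs:subClassOf kb:Evidence .

kb:label_itself a owl:Class ; rdfs:subClassOf kb:SimilarityEvidence ;
    rdfs:label "Itself"@en .
kb:label_rel_exact_approx a owl:Class ; rdfs:subClassOf kb:SimilarityEvidence ;
    rdfs:label "Relatedness by exact/approximate match"@en .
kb:label_rel_inexact_hierarchy a owl:Class ; rdfs:subClassOf kb:SimilarityEvidence ;
    rdfs:label "Relatedness by inexact match (hypernym/hyponym) or (hyponym/hypernym)"@en .
kb:label_rel_inexact_background a owl:Class ; rdfs:subClassOf kb:CurationEvidence ;
    rdfs:label "Relatedness by inexact match (background knowledge)"@en .
kb:label_unrel_not_clinical a owl:Class ; rdfs:subClassOf kb:CurationEvidence ;
    rdfs:label "Unrelated: not clinically meaningful"@en .
kb:label_unrel_excluded a owl:Class ; rdfs:subClassOf kb:CurationEvidence ;
    rdfs:label "Unrelated: excluded"@en .
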