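<?xml version="1.0" encoding="UTF-8"?>
<!-- Schema for the PLGS-like identification dialect read by protinfer.
     The vendor's own schema is proprietary; this documented stand-in
     carries the same information content: proteins with nested peptide
     occurrences, scores and modification variants. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:element name="results">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="protein" type="proteinType" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string" use="optional"/>
    </xs:complexType>
  </xs:element>

  <xs:complexType name="proteinType">
    <xs:sequence>
      <xs:element name="peptide" type="peptideType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="accession" type="xs:string" use="required"/>
    <xs:attribute name="description" type="xs:string" use="optional"/>
  </xs:complexType>

  <xs:complexType name="peptideType">
    <xs:sequence>
      <xs:element name="modification" type="modificationType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="sequence" use="required">
      <xs:simpleType>
        <xs:restriction base="xs:string">
          <xs:pattern value="[A-Z]+"/>
        </xs:restriction>
      </xs:simpleType>
    </xs:attribute>
    <xs:attribute name="score" type="xs:double" use="optional"/>
  </xs:complexType>

  <xs:complexType name="modificationType">
    <xs:attribute name="position" type="xs:positiveInteger" use="required"/>
    <xs:attribute name="name" type="xs:string" use="required"/>
  </xs:complexType>

</xs:schema>
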