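<?xml version="1.0" encoding="UTF-8"?>
<!-- Glossary interchange dialect: one glossary per document, terms with a
     word type, an optional semantic identifier, and numbered definitions. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="wordTypeType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="no_type"/>
      <xs:enumeration value="chemical"/>
      <xs:enumeration value="protein"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="identifierKindType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="inchi"/>
      <xs:enumeration value="pdb_id"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="fieldIndexType">
    <xs:restriction base="xs:positiveInteger">
      <xs:maxInclusive value="5"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="glossary">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="term" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="name" type="xs:string"/>
              <xs:element name="word_type" type="wordTypeType"/>
              <xs:element name="identifier" minOccurs="0">
                <xs:complexType>
                  <xs:simpleContent>
                    <xs:extension base="xs:string">
                      <xs:attribute name="kind" type="identifierKindType" use="required"/>
                    </xs:extension>
                  </xs:simpleContent>
                </xs:complexType>
              </xs:element>
              <xs:element name="definition" minOccurs="0" maxOccurs="5">
                <xs:complexType>
                  <xs:simpleContent>
                    <xs:extension base="xs:string">
                      <xs:attribute name="index" type="fieldIndexType" use="required"/>
                      <xs:attribute name="locked" type="xs:boolean" default="false"/>
                    </xs:extension>
                  </xs:simpleContent>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="name" type="xs:string" use="required"/>
      <xs:attribute name="field_count" type="fieldIndexType" use="required"/>
      <xs:attribute name="source_citation" type="xs:string"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
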